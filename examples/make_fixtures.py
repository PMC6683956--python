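"""Write the deterministic synthetic fixture suite.

Produces CSV observation sets for free curcumin (k_C = 200) and
release-product mixtures (k_C = 75, k_CM = 25, 40% monoacrylate) at 10 and
100 mM AAPH, noiseless and with σ = 0.02, plus a manifest of generating
parameters and seeds. Same seed ⇒ byte-identical files.
"""

from radscav import generate_fixture_suite

manifest = generate_fixture_suite("scratch/fixtures", base_seed=0)
for rec in manifest:
    print(f"{rec['file']}: kind={rec['kind']} aaph={rec['aaph_mM']:g} mM "
          f"sigma={rec['sigma']:g} seed={rec['seed']}")
print()
print(f"{len(manifest)} fixtures written to scratch/fixtures/ "
      "(see manifest.txt for full parameter records)")
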