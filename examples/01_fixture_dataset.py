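"""Generate a small synthetic nut-like dataset and inspect its manifest.

Eight parametric shape families (ellipse, ridged ellipse, hexagon,
speckled blob, annulus, star, textured rectangle, crescent) stand in for
the eight nut classes; identical specs give byte-identical pixels.
"""

from nutnet.fixtures import FixtureSpec, generate_fixture_dataset

spec = FixtureSpec(n_classes=8, n_per_class=10, image_size=64, seed=0)
manifest = generate_fixture_dataset(spec, "runs/example_fixtures")

print(f"wrote {len(manifest)} images into runs/example_fixtures/")
for cname in manifest.class_names:
    print(f"  {cname:12s} {manifest.count(class_label=cname)} images")
print("Each class uses a fixed shape/texture family, so a small CNN can "
      "tell them apart; per-image jitter is seeded for reproducibility.")
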