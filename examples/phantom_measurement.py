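"""Generate a synthetic axial slice and recover its known fat content.

The phantom has four elliptical muscle regions (paraspinal and psoas, per
side) with known fat fractions. On a clean image the measured fat
infiltration must match the ground truth exactly.
"""

from lumbarfi import default_spec, generate_phantom, measure_all

phantom = generate_phantom(default_spec(seed=11))
results = measure_all(phantom.image, phantom.masks)

print("muscle  CSA[cm^2]  fCSA[cm^2]  FAT[cm^2]  FI[%]")
for muscle, comp in results.items():
    print(
        f"{muscle:6s}  {comp.CSA:8.2f}  {comp.fCSA:9.2f}  {comp.FAT:8.2f}  {comp.FI:5.1f}"
    )
print()
print("Ground-truth fat fractions per region:")
for (muscle, side), frac in phantom.truth_fat_fraction.items():
    print(f"  {muscle:5s} {side:5s}: {100 * frac:5.2f} %")
print()
print("The bilateral FI printed above is the area-weighted combination of the")
print("two sides, so it reproduces the per-region truth without error on a")
print("noiseless, shading-free image.")
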