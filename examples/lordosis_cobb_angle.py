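"""Lumbar lordosis as the Cobb angle between two endplate lines.

Lordosis enters the analysis as a number measured on a lateral radiograph:
the unsigned angle between the superior endplate of L1 and the superior
endplate of S1, each given by two landmark points.
"""

from lumbarfi import EndplateLandmarks, cobb_angle

# landmark coordinates (x, y) in image units, two points per endplate
landmarks = EndplateLandmarks(
    L1_superior=((102.0, 40.0), (148.0, 33.0)),
    S1_superior=((95.0, 210.0), (150.0, 255.0)),
)
angle = cobb_angle(landmarks)
print(f"Cobb angle L1-S1: {angle:.1f} degrees")
print()
print("Typical lumbar lordosis in adults is roughly 40-60 degrees; the value")
print("is unsigned and never exceeds 90.")
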