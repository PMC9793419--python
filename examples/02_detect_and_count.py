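"""Detect single-molecule spots and convert them to absolute molecule counts.

Renders a small embryo with known molecule positions, runs band-pass +
3D-Gaussian-fit detection, matches detections to the ground truth, then
decomposes bright detections into integer molecule counts using the
estimated single-molecule reference intensity.
"""

from memfish import (
    LocalizationModel,
    NoiseModel,
    decompose,
    detect_spots,
    distance_field,
    estimate_reference,
    generate_geometry,
    match_to_truth,
    place_spots,
    render_stack,
    total_molecules,
)

geom = generate_geometry(2, (24, 128, 128), (0.2, 0.1, 0.1), seed=2)
field = distance_field(geom.label_volume, geom.voxel_size)
truth = place_spots(geom, LocalizationModel(mode="uniform"), 500, seed=3, dist=field)
stack = render_stack(
    geom, truth, spot_amplitude=150.0,
    noise=NoiseModel(poisson=False, gaussian_sd=30.0, baseline=100.0),  # peak SNR 5
    seed=4,
)

spots = detect_spots(stack.channel("smFISH"), geom.voxel_size, threshold=5.0)
match = match_to_truth(spots, truth, tolerance=0.3)
ref = estimate_reference(spots)
counted = decompose(spots, ref)

print(f"planted molecules : {len(truth)}")
print(f"detections        : {len(spots)}")
print(f"precision / recall: {match.precision:.3f} / {match.recall:.3f}")
print(f"mean position err : {match.mean_error_um * 1000:.0f} nm")
print(f"reference molecule: {ref.intensity:.0f} ± {ref.intensity_spread:.0f} counts")
print(f"decomposed total  : {total_molecules(counted)} molecules")
print(
    "\nDetections lost to diffraction-limited merging are recovered by the\n"
    "intensity decomposition: the decomposed total, not the raw detection\n"
    "count, is the per-embryo mRNA abundance."
)
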