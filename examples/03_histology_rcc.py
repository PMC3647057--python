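"""Quantify red-cell congestion on synthetic eosin histology.

Generates sections for grafts harvested 0/1/2 h after donor cardiac death
(CD0h/CD1h/CD2h), segments congested pixels by redness thresholding, and
reports per-compartment congested-area fractions. Pre-transplant, congestion
is massive in the inner stripe (IS) of CD1h and CD2h kidneys but mild in CD0h.
"""

import renalqmri as rq

label_map = rq.make_label_map((256, 128))

print("condition   CTX     OS      IS      IM     (measured congested fraction)")
for cond in rq.CONDITIONS:
    preset = rq.table_preset(cond)
    h = rq.make_histology_sample(label_map, preset.rcc_severity, seed=10)
    quant = rq.quantify_rcc(h.rgb_image, label_map)  # redness > 95, blobs >= 5 px
    f = quant.fraction
    print(f"  {cond}    {f['CTX']:.3f}   {f['OS']:.3f}   {f['IS']:.3f}   {f['IM']:.3f}")

# segmentation quality against the generator's ground truth
h = rq.make_histology_sample(label_map, rq.table_preset("CD2h").rcc_severity, seed=10)
mask = rq.segment_rcc(h.rgb_image)
dice = 2 * (mask & h.rcc_truth).sum() / (mask.sum() + h.rcc_truth.sum())
print(f"\nDice vs ground truth: {dice:.3f} (>= 0.95 expected on synthetic stains)")
print("Expected pattern: IS fraction ~0.35-0.40 for CD1h/CD2h vs ~0.03 for CD0h.")
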