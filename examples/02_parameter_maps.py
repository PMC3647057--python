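"""Recover T2* and ADC maps from simulated signals and summarize per compartment.

On noiseless data the log-linear T2* fit and the two-point ADC formula invert
the forward model exactly, so the ROI means reproduce the assigned
ground-truth values; with noise they scatter around them.
"""

import renalqmri as rq

preset = rq.table_preset("CD0h").with_zero_sd()  # compartments carry the reference means exactly
phantom = rq.make_kidney_phantom(preset=preset, seed=0)
acq = rq.AcquisitionConfig(te_list_ms=(5.0, 10.0, 20.0, 40.0, 80.0))

t2map = rq.fit_t2star(rq.simulate_gre(phantom, acq))
adcmap = rq.compute_adc_map(rq.simulate_dwi(phantom, acq), b_low=0.0, b_high=134.0)

rois = rq.derive_rois(phantom.label_map, mode="from_labels")
t2 = rq.transfer_roi(rois, t2map, kidney_id="demo")
adc = rq.transfer_roi(rois, adcmap, kidney_id="demo")

print("compartment  T2* [ms]   ADC [1e-3 mm^2/s]   (noiseless round trip)")
for comp in rq.COMPARTMENTS:
    print(f"  {comp:4s}      {t2.mean[comp]:7.1f}       {adc.mean[comp]:6.3f}")
print("IM T2* should read 218.1 ms and IM ADC 0.985 — the assigned reference values.")

# with Rician noise the estimates are no longer exact
noisy = rq.add_noise(rq.simulate_gre(phantom, acq), sigma=15.0, model="rician", seed=4, n_averages=2)
t2n = rq.transfer_roi(rois, rq.fit_t2star(noisy), kidney_id="noisy")
print("\nwith sigma=15 Rician noise, two averages:")
for comp in rq.COMPARTMENTS:
    print(f"  {comp:4s}  T2* {t2n.mean[comp]:7.1f} ms "
          f"({t2n.n_invalid[comp]} invalid px excluded)")
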