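"""The nine vegetation indices at plot level on a synthetic scene.

Each plot's index is evaluated on its mean ROI reflectance.  NDVI rises with
leaf abundance; NDYI (green-blue yellowness) responds to the flower
fraction, which is why it matters for flowering rapeseed.
"""

from rapeyield import (
    TrialDesign,
    VI_NAMES,
    generate_trial,
    plot_aggregate,
    render_scene,
    unmix_image,
)

bundle = generate_trial(TrialDesign(seed=1))
scene, _ = render_scene(bundle, snr_db=40.0, seed=2)
abundance = unmix_image(scene, bundle.endmember_matrix)
table = plot_aggregate(scene, abundance, bundle.plots)

cols = ["plot_id", "nitrogen_rate", "abd_FL", "abd_LF"] + list(VI_NAMES)
print(table[cols].round(3).to_string(index=False))
print("\nEach row is one plot; indices come from the plot-mean reflectance "
      "and abd_* from FCLS unmixing.")
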