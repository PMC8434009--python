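"""Amplitude QC: inject artifacts into a clean recording and watch the
three-level rejection rules fire.

An epoch is bad when its absolute amplitude exceeds 80 uV; a selection is
contaminated when more than half its epochs are bad; a subject is excluded
when 10 of 15 selections in either environment are contaminated.
"""

import dataclasses

from p300bci import (
    ErpTemplate,
    NoiseModel,
    ParadigmConfig,
    PipelineConfig,
    RunConfig,
    flag_bad_epochs,
    flag_contaminated_selection,
    inject_artifacts,
    single_trial_epochs,
)
from p300bci.experiment import simulate_selection

config = RunConfig(template=ErpTemplate(peak_amplitude_uv=5.0))
rec = simulate_selection(config, target=2, n_blinks=20, seed=5)

for rate in (0.0, 10.0, 120.0):
    noisy = inject_artifacts(
        rec, dataclasses.replace(config.noise, artifact_rate_per_min=rate,
                                 artifact_amplitude_uv=120.0, seed=8)
    )
    epochs = single_trial_epochs(noisy, PipelineConfig(), resample=False)
    bad = flag_bad_epochs(epochs)
    contaminated = flag_contaminated_selection(bad)
    print(
        f"artifact rate {rate:5.1f}/min: {int(bad.sum()):3d} of {len(epochs)} epochs bad"
        f" -> selection contaminated: {contaminated}"
    )

# With no artifacts nothing is flagged; occasional 120 uV transients flag the
# epochs they touch; a pathological rate pushes the selection over the strict
# 50% rule.
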