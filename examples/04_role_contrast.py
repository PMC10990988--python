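"""The verb-bias dissociation: raw contrast vs factorized component.

A verb-biased cohort of estimated RDMs hides thematic-role information from
the raw semantic-overlap-controlled contrast, while the stability-NMF
component most correlated with the agent/patient models still exposes it —
the core argument for factorizing similarity judgments.
"""

import numpy as np

from multiarrange import build_ensemble, generate_stimulus_set, stability_cluster
from multiarrange.analysis import (
    contrast_test,
    role_controlled_contrast,
    subject_contrast_differences,
)
from multiarrange.factorization import component_model_correlation
from multiarrange.rater_sim import default_dimensions, mixture_cohort_rdms

stimuli = generate_stimulus_set(seed=1)
dims = default_dimensions(stimuli)
rdms, _, _ = mixture_cohort_rdms(dims, n_subjects=30, seed=0)

diffs = subject_contrast_differences(rdms, stimuli)
t_raw, p_raw = contrast_test(diffs)
print(f"raw per-subject contrast: mean diff {np.mean(diffs):+.4f}, "
      f"one-sided p = {p_raw:.3f}")

solution = stability_cluster(build_ensemble(rdms), 5, n_restarts=20, seed=0)
agent, patient = dims["agent_category"], dims["patient_category"]
scores = [
    component_model_correlation(c, agent) + component_model_correlation(c, patient)
    for c in solution.centroids
]
best = int(np.nanargmax(scores))
result = role_controlled_contrast(solution.centroids[best], stimuli)
print(f"role component (agent+patient rho sum {scores[best]:.2f}): "
      f"mean diff {result.mean_difference:+.4f} over {len(result.pairings)} pairings")
print("positive differences mean sentences sharing a noun category in the "
      "same thematic role are judged more similar than sharing it in the "
      "opposite role — visible in the component even when the raw contrast "
      "is washed out by verb-dominant attention")
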