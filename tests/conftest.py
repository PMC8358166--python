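import numpy as np
import pytest

from phenorow.fixtures import FieldConfig


def f1_score_masks(pred: np.ndarray, truth: np.ndarray) -> float:
    """Pixel F1 between two binary masks."""
    p = np.asarray(pred) > 0
    t = np.asarray(truth) > 0
    tp = int((p & t).sum())
    fp = int((p & ~t).sum())
    fn = int((~p & t).sum())
    return 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 1.0


@pytest.fixture
def small_field_config():
    """A 400×300 field scene with 4 well-separated plants."""
    return FieldConfig(
        height=300, width=400, n_plants=4, margin=60, min_gap=90,
        stem_halfwidth=4, max_halfwidth=20,
    )


def brute_force_segments(profile, rel_threshold, min_gap):
    """Independent oracle for peak-segment calling.

    Labels every strictly-above-threshold index, groups consecutive
    labeled indices, merges groups separated by fewer than ``min_gap``
    below-threshold indices, and takes each group's profile argmax.
    """
    profile = list(profile)
    thr = rel_threshold * max(profile)
    above = [i for i, v in enumerate(profile) if v > thr]
    groups: list[list[int]] = []
    for i in above:
        if groups and i - groups[-1][-1] - 1 < min_gap:
            groups[-1].append(i)
        else:
            groups.append([i])
    segments, peaks = [], []
    for g in groups:
        s, e = g[0], g[-1]
        segments.append((s, e))
        best = max(range(s, e + 1), key=lambda i: (profile[i], -i))
        peaks.append(best)
    return segments, peaks
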