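"""Shared fixtures: small rendered fields with ground truth.

Everything is generated at test time from seeded specs; no binary
fixtures are stored.
"""

from __future__ import annotations

import numpy as np
import pytest

from mdscreen.benchmarks import match_cells_to_truth  # noqa: F401
from mdscreen.imaging import segment_field
from mdscreen.synthetic import FieldSpec, render_field


@pytest.fixture(scope="session")
def standard_field():
    """One 20-cell field at the standard acquisition settings (SNR 10)."""
    spec = FieldSpec(n_cells=20, nucleoid_count_mean=40, seed=7)
    image, truth = render_field(spec)
    return spec, image, truth


@pytest.fixture(scope="session")
def noisefree_field():
    spec = FieldSpec(n_cells=10, nucleoid_count_mean=30, seed=42, noise_sd=0)
    image, truth = render_field(spec)
    return spec, image, truth


def matched_counts(fields_with_truth):
    """Per-cell (truth, measured) nucleoid counts across fields."""
    from mdscreen.imaging import quantify_field

    truths, measured = [], []
    for image, truth in fields_with_truth:
        seg = segment_field(image)
        rec = quantify_field(image)
        match = match_cells_to_truth(seg, truth)
        truths += [truth[match[cid]].nucleoid_count for cid in rec.cell_id]
        measured += rec.nucleoid_count.tolist()
    return np.asarray(truths), np.asarray(measured)
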