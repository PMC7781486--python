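"""Shared fixtures: the four published worked examples and fast SSA configs."""

from __future__ import annotations

import numpy as np
import pytest

from bladesim.circuits import CircuitDesign

# The four published worked examples: observed vector, circuit genes,
# ideal vector, printed theta, printed theta_bar, n.  Printed metric
# values derive from unrounded source data; thetas recomputed from the
# rounded printed vectors agree to the stated tolerances.
WORKED_EXAMPLES = [
    dict(
        observed=[42, 53, 34, 46, 44, 59, 55, 69],
        genes=["GFPmCherry"] * 4,
        ideal=[100] * 8,
        theta=11.58,
        theta_bar=1.45,
        n=8,
        theta_tol=0.02,  # absolute, degrees: printed vector reproduces theta
    ),
    dict(
        observed=[0, 0, 0, 2, 0, 0, 0, 89],
        genes=["STOP", "STOP", "STOP", "mCherry"],
        ideal=[0, 0, 0, 0, 0, 0, 0, 100],
        theta=1.29,
        theta_bar=1.29,
        n=1,
        theta_tol=None,  # relative 1.5%
    ),
    dict(
        observed=[67, 76, 60, 2, 6, 13, 77, 0],
        genes=["GFPmCherry", "GFP", "STOP", "GFP"],
        ideal=[100, 100, 100, 0, 0, 0, 100, 0],
        theta=8.2,
        theta_bar=2.04,
        n=4,
        theta_tol=None,
    ),
    dict(
        observed=[63, 73, 1, 7, 4, 88, 0, 92],
        genes=["GFPmCherry", "STOP", "mCherry", "mCherry"],
        ideal=[100, 100, 0, 0, 0, 100, 0, 100],
        theta=8.9,
        theta_bar=2.22,
        n=4,
        theta_tol=None,
    ),
]


@pytest.fixture(params=range(4), ids=lambda i: f"worked_example_{i + 1}")
def worked_example(request):
    ex = dict(WORKED_EXAMPLES[request.param])
    ex["circuit"] = CircuitDesign.from_labels(ex["genes"])
    ex["observed"] = np.asarray(ex["observed"], dtype=float)
    return ex
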