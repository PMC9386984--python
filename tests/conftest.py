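"""Shared fixtures: simulated study data reused across test modules.

The two MCMC fixtures are session-scoped because they are the expensive
part of the suite; every test that inspects them treats them as read-only.
"""

from __future__ import annotations

import numpy as np
import pytest

from repeatcn.control_fit import fit_controls, summarise_bias
from repeatcn.countmatrix import select_loci
from repeatcn.rcn_infer import infer_rcn
from repeatcn.simulate import (
    simulate_bias,
    simulate_control_counts,
    simulate_rcn_sample,
    simulate_study,
    synthetic_loci,
)

CONTROL_IDS = [f"ctrl{k}" for k in range(8)]

#: the four-state copy-number fixture: 250 loci per state, states interleaved
#: across eight chromosome arms, counts at the depth of one sequencing run
FOUR_STATE_SEGMENTS = [(125, 1.0), (125, 3.0), (125, 0.5), (125, 1.5)] * 2
FOUR_STATE_RCNS = (0.5, 1.0, 1.5, 3.0)


@pytest.fixture(scope="session")
def control_panel():
    """8 simulated diploid controls (L=500, n=2e5, s=1e4) plus the MH fit."""
    cm, m, _ = simulate_study(L=500, n_controls=8, reads=200_000, s=1e4, seed=11)
    sel = select_loci(cm, CONTROL_IDS)
    kept = cm.loci.merge(
        sel.loci, on=["chrom", "pos", "strand"], how="left", indicator=True
    )["_merge"].eq("both")
    m_true = m[kept.to_numpy()]
    m_true = m_true / m_true.sum()
    trace = fit_controls(sel, CONTROL_IDS, iters=4000, burn=1000, seed=1)
    return {
        "cm": sel,
        "m_true": m_true,
        "s_true": 1e4,
        "trace": trace,
        "bias": summarise_bias(trace),
    }


@pytest.fixture(scope="session")
def four_state_run():
    """Sampler output on a high-purity 4-state profile with known truth."""
    L = 1000
    loci = synthetic_loci(L, seed=5)
    m = simulate_bias(L, seed=6)
    y, truth = simulate_rcn_sample(
        m, s_tilde=1e4, n=2_000_000, segments=FOUR_STATE_SEGMENTS, purity=1.0, seed=7
    )
    trace = infer_rcn(y, loci["arm"], m, iters=5000, burn=1000, thin=5, seed=3, loci=loci)
    return {"loci": loci, "m": m, "y": y, "truth": truth, "trace": trace}


@pytest.fixture(scope="session")
def null_run():
    """Sampler output on a copy-number-flat sample (purity 0)."""
    L = 400
    loci = synthetic_loci(L, seed=31)
    m = simulate_bias(L, seed=32)
    y, truth = simulate_rcn_sample(
        m, s_tilde=1e4, n=2_000_000, segments=[(L, 1.0)], purity=0.0, seed=33
    )
    trace = infer_rcn(y, loci["arm"], m, iters=1500, burn=500, thin=2, seed=34, loci=loci)
    return {"loci": loci, "m": m, "truth": truth, "trace": trace}
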