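"""Shared fixtures: a small synthetic study system and scorer-recovery runs.

Everything is generated programmatically from fixed seeds; session scope
keeps the expensive pieces (landscape generation, replicated scorer fits)
computed once.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from streamvuln import (
    FactorParams,
    NicheSpread,
    SpeciesNiche,
    SuitabilitySurface,
    auc_score,
    default_anomalies,
    default_baseline,
    fit_scorer,
    generate_landscape,
    generate_scenarios,
    generate_species_truth,
    sample_occurrences,
)


@pytest.fixture(scope="session")
def landscape():
    return generate_landscape(20, 20, 10.0, 40, 0.2, seed=1)


@pytest.fixture(scope="session")
def stacks(landscape):
    return generate_scenarios(
        landscape, default_baseline(), default_anomalies(), seed=2
    )


@pytest.fixture(scope="session")
def current(stacks):
    return stacks[0]


@pytest.fixture(scope="session")
def niche(current, landscape):
    return generate_species_truth(1, current, seed=3, landscape=landscape)[0]


@pytest.fixture(scope="session")
def occurrences(niche, landscape, current):
    return sample_occurrences(niche, landscape, current, 120, 2.0, seed=4)


def surface(values, tau=0.5, species="sp", scenario="current"):
    """Helper: build a SuitabilitySurface from a dict or Series."""
    if isinstance(values, dict):
        values = pd.Series(values)
    return SuitabilitySurface(
        species=species, scenario=scenario, values=values.astype(float),
        tss_threshold=tau,
    )


@pytest.fixture(scope="session")
def recovery_runs():
    """Strong-signal scorer recovery: 20 seeded replicates.

    Each replicate draws a species with peak 0.95 and tolerances at half
    the spatial SD of each factor, samples presences from its occupancy and
    background absences from the landscape at large, fits the built-in
    scorer on a 70/30 split and evaluates AUC on the held-out 30%.  The
    recovery landscape carries 250 subcatchments, and its factors are
    noise-dominated (no shared spatial gradients): the default baseline's
    strongly correlated temperature factors leave per-factor optima
    under-identified for any estimator, so the recovery check runs where
    the optima are statistically identifiable.
    """
    ls = generate_landscape(30, 30, 10.0, 250, 0.1, seed=100)
    base = default_baseline()
    independent = {
        f: FactorParams(p.mean, noise_sd=max(p.noise_sd, 0.05 * abs(p.mean)),
                        nonnegative=p.nonnegative)
        for f, p in base.items()
    }
    stack = generate_scenarios(ls, independent, {}, seed=101)[0]
    env = stack.factors
    sd = env.std(ddof=0)
    n = 300
    runs = []
    for seed in range(20):
        rng = np.random.default_rng(1000 + seed)
        anchor = env.iloc[rng.integers(len(env))]
        truth = SpeciesNiche(
            species=f"rec{seed}",
            optima=anchor.astype(float),
            tolerances=(0.5 * sd).astype(float),
            peak=0.95,
        )
        occ = sample_occurrences(truth, ls, stack, n, 0.0, seed=seed)
        pres = occ.records[["subcatchment", "x", "y"]]
        abs_subs = rng.choice(env.index.to_numpy(), size=n)
        absc = pd.DataFrame({"subcatchment": abs_subs})
        absc["x"] = 0.0
        absc["y"] = 0.0
        idx = rng.permutation(n)
        n_tr = int(0.7 * n)
        tr, te = idx[:n_tr], idx[n_tr:]
        model = fit_scorer(pres.iloc[tr], absc.iloc[tr], stack)
        sp = model.predict(env.loc[pres.iloc[te]["subcatchment"]])
        sa = model.predict(env.loc[absc.iloc[te]["subcatchment"]])
        runs.append({"truth": truth, "model": model, "auc": auc_score(sp, sa)})
    return runs
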