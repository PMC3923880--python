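"""Habitat-suitability surfaces: scorer fitting, evaluation, ensembling.

The multi-algorithm SDM ensemble is abstracted behind a scorer interface:
anything mapping a per-subcatchment factor table to scores in [0, 1] can be
a member.  The built-in scorer is a Gaussian-niche model fitted by maximum
likelihood on presence/pseudo-absence labels.  Around the scorers sit the
operations that matter for the vulnerability assessment itself: targeted
pseudo-absence selection, AUC/TSS evaluation with a TSS-maximised binary
threshold, TSS-weighted ensemble projection, and environmental clamping of
projections outside training limits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .landscape import Landscape, OccurrenceSet, ScenarioStack


@dataclass
class SuitabilitySurface:
    """Per-subcatchment suitability in [0, 1] for one species and scenario,
    with the TSS-maximising binary threshold tau attached."""

    species: str
    scenario: str
    values: pd.Series
    tss_threshold: float

    def copy_with(self, values=None, scenario=None) -> "SuitabilitySurface":
        return SuitabilitySurface(
            species=self.species,
            scenario=self.scenario if scenario is None else scenario,
            values=self.values if values is None else values,
            tss_threshold=self.tss_threshold,
        )


@dataclass
class EvaluationResult:
    auc: float
    tss: float
    tss_threshold: float


def aggregate_to_subcatchments(cell_values: np.ndarray, landscape: Landscape) -> pd.Series:
    """Arithmetic mean of a per-cell field over each subcatchment's cells."""
    land = ~landscape.is_water
    vals = np.asarray(cell_values, dtype=float)
    if np.isnan(vals[land]).any():
        raise ValueError("every land cell must have a value")
    codes = landscape.sub_index[land]
    sums = np.bincount(codes, weights=vals[land], minlength=landscape.n_subcatchments)
    counts = np.bincount(codes, minlength=landscape.n_subcatchments)
    if np.any(counts == 0):
        bad = landscape.subcatchments["id"].iloc[int(np.argmin(counts))]
        raise ValueError(f"subcatchment {bad} has no valued cells")
    return pd.Series(
        sums / counts,
        index=pd.Index(landscape.subcatchments["id"], name="subcatchment"),
    )


def select_pseudo_absences(
    target_occ: OccurrenceSet,
    background: pd.DataFrame,
    landscape: Landscape,
    radius_km: float = 300.0,
    n_total: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Targeted pseudo-absence selection.

    Background localities (where *other* species were collected) within
    ``radius_km`` of any presence record — the range considered reachable
    under current conditions — are the preferred absences because they share
    the presences' sampling bias; localities in a subcatchment where the
    target is present are excluded.  If the eligible pool is smaller than
    ``n_total`` it is supplemented by randomly selected subcatchment
    centroids from the rest of the landscape so the absence total is
    standardised across species.

    Parameters
    ----------
    background : DataFrame with columns subcatchment, x, y.

    Returns a DataFrame (subcatchment, x, y, source) with source in
    {"background", "supplement"}.
    """
    if len(background) == 0:
        raise ValueError("background locality list is empty")
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    rng = np.random.default_rng(seed)
    pres = target_occ.records
    pres_subs = set(pres["subcatchment"])

    bx = background["x"].to_numpy()
    by = background["y"].to_numpy()
    d2min = np.full(len(background), np.inf)
    for px, py in zip(pres["x"].to_numpy(), pres["y"].to_numpy()):
        d2min = np.minimum(d2min, (bx - px) ** 2 + (by - py) ** 2)
    within = d2min <= radius_km**2
    outside_pres = ~background["subcatchment"].isin(pres_subs).to_numpy()
    eligible = background.loc[within & outside_pres, ["subcatchment", "x", "y"]]
    eligible = eligible.drop_duplicates(subset=["x", "y"]).reset_index(drop=True)

    if len(eligible) >= n_total:
        take = rng.choice(len(eligible), size=n_total, replace=False)
        out = eligible.iloc[np.sort(take)].copy()
        out["source"] = "background"
        return out.reset_index(drop=True)

    out = eligible.copy()
    out["source"] = "background"
    need = n_total - len(out)
    sc = landscape.subcatchments
    pool = sc.loc[
        ~sc["id"].isin(pres_subs) & ~sc["id"].isin(set(eligible["subcatchment"])),
        ["id", "centroid_x", "centroid_y"],
    ]
    if need > len(pool):
        raise ValueError(
            f"n_total={n_total} exceeds eligible background ({len(eligible)}) "
            f"plus available supplements ({len(pool)})"
        )
    take = rng.choice(len(pool), size=need, replace=False)
    supp = pool.iloc[np.sort(take)].rename(
        columns={"id": "subcatchment", "centroid_x": "x", "centroid_y": "y"}
    )
    supp["source"] = "supplement"
    return pd.concat([out, supp], ignore_index=True)


class GaussianNicheScorer:
    """Product-Gaussian niche response fitted by maximum likelihood.

    P(presence | v) = peak * prod_f exp(-0.5 ((v_f - opt_f) / tol_f)^2)

    fitted on Bernoulli labels with L-BFGS-B over (optimum, log tolerance)
    per factor plus logit(peak).  Factors are standardised internally; a
    factor with zero variance in the training data is dropped with a
    warning.  Estimated optima/tolerances are exposed in raw factor units
    for parameter-recovery diagnostics.
    """

    label = "gaussian-niche"

    def __init__(self):
        self.factors_: list = []
        self.training_limits: dict = {}
        self.optima_: pd.Series | None = None
        self.tolerances_: pd.Series | None = None
        self.peak_: float | None = None
        self._mu = None
        self._sd = None
        self._theta = None

    def fit(self, X: pd.DataFrame, y: np.ndarray) -> "GaussianNicheScorer":
        y = np.asarray(y, dtype=float)
        if (y == 1).sum() < 2 or (y == 0).sum() < 2:
            raise ValueError("need at least 2 presences and 2 absences")
        keep = []
        for f in X.columns:
            if np.ptp(X[f].to_numpy()) == 0:
                warnings.warn(
                    f"factor {f!r} has zero variance in training data; dropped",
                    stacklevel=2,
                )
            else:
                keep.append(f)
        if not keep:
            raise ValueError("all factors degenerate; nothing to fit")
        self.factors_ = keep
        self.training_limits = {
            f: (float(X[f].min()), float(X[f].max())) for f in keep
        }
        Xk = X[keep].to_numpy(dtype=float)
        self._mu = Xk.mean(axis=0)
        self._sd = Xk.std(axis=0)
        Z = (Xk - self._mu) / self._sd
        m = len(keep)

        zp = Z[y == 1]
        u0 = zp.mean(axis=0)
        s0 = np.clip(zp.std(axis=0), 0.15, 5.0)
        bounds = [(-10, 10)] * m + [(np.log(0.05), np.log(50.0))] * m + [(-8, 8)]

        def nll(theta):
            u, logs, a = theta[:m], theta[m : 2 * m], theta[-1]
            q = ((Z - u) / np.exp(logs)) ** 2
            logg = -0.5 * q.sum(axis=1)
            peak = 1.0 / (1.0 + np.exp(-a))
            p = np.clip(peak * np.exp(logg), 1e-12, 1 - 1e-12)
            return -(y * np.log(p) + (1 - y) * np.log(1 - p)).sum()

        # multi-start: presence-moment init plus wider/tighter tolerance
        # starts guards against occasional L-BFGS local minima
        starts = [
            np.concatenate([u0, np.log(s0), [2.0]]),
            np.concatenate([u0, np.log(np.clip(0.5 * s0, 0.05, 50.0)), [1.0]]),
            np.concatenate([u0, np.log(np.clip(2.0 * s0, 0.05, 50.0)), [2.0]]),
        ]
        best = None
        for theta0 in starts:
            res = optimize.minimize(nll, theta0, method="L-BFGS-B", bounds=bounds)
            if best is None or res.fun < best.fun:
                best = res
        self._theta = best.x
        res = best
        u, logs, a = res.x[:m], res.x[m : 2 * m], res.x[-1]
        self.optima_ = pd.Series(self._mu + self._sd * u, index=keep)
        self.tolerances_ = pd.Series(self._sd * np.exp(logs), index=keep)
        self.peak_ = float(1.0 / (1.0 + np.exp(-a)))
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        if self._theta is None:
            raise RuntimeError("scorer is not fitted")
        z = (X[self.factors_].to_numpy(dtype=float) - self._mu) / self._sd
        m = len(self.factors_)
        u, logs = self._theta[:m], self._theta[m : 2 * m]
        q = ((z - u) / np.exp(logs)) ** 2
        return self.peak_ * np.exp(-0.5 * q.sum(axis=1))


_SCORERS = {"gaussian": GaussianNicheScorer}


def register_scorer(kind: str, factory) -> None:
    """Register an externally supplied scorer factory under a model kind."""
    _SCORERS[kind] = factory


def fit_scorer(
    presences: pd.DataFrame,
    absences: pd.DataFrame,
    env: ScenarioStack,
    model_kind: str = "gaussian",
):
    """Fit a suitability scorer on presence/absence localities.

    Localities are DataFrames with a ``subcatchment`` column; features are
    looked up in the scenario stack.
    """
    if model_kind not in _SCORERS:
        raise ValueError(f"unknown model kind {model_kind!r}")
    Xp = env.factors.loc[presences["subcatchment"]]
    Xa = env.factors.loc[absences["subcatchment"]]
    X = pd.concat([Xp, Xa], ignore_index=True)
    y = np.concatenate([np.ones(len(Xp)), np.zeros(len(Xa))])
    return _SCORERS[model_kind]().fit(X, y)


def auc_score(pres_scores: np.ndarray, abs_scores: np.ndarray) -> float:
    """Rank-based AUC (probability a presence outscores an absence),
    midrank convention for ties."""
    pres_scores = np.asarray(pres_scores, dtype=float)
    abs_scores = np.asarray(abs_scores, dtype=float)
    n1, n0 = len(pres_scores), len(abs_scores)
    ranks = stats.rankdata(np.concatenate([pres_scores, abs_scores]))
    r1 = ranks[:n1].sum()
    return float((r1 - n1 * (n1 + 1) / 2) / (n1 * n0))


def evaluate(model, test_presences: pd.DataFrame, test_absences: pd.DataFrame,
             env: ScenarioStack) -> EvaluationResult:
    """AUC plus the TSS maximum over all distinct predicted scores.

    TSS = sensitivity + specificity - 1 with "score >= threshold" counted
    suitable; the smallest score achieving the maximum is returned as the
    threshold.
    """
    if len(test_presences) == 0 or len(test_absences) == 0:
        raise ValueError("both test sets must be non-empty")
    sp = model.predict(env.factors.loc[test_presences["subcatchment"]])
    sa = model.predict(env.factors.loc[test_absences["subcatchment"]])
    auc = auc_score(sp, sa)
    tss, tau = max_tss_threshold(sp, sa)
    return EvaluationResult(auc=auc, tss=tss, tss_threshold=tau)


def max_tss_threshold(pres_scores, abs_scores):
    """Scan every distinct score as a candidate threshold; return
    (max TSS, smallest maximising threshold)."""
    sp = np.asarray(pres_scores, dtype=float)
    sa = np.asarray(abs_scores, dtype=float)
    cands = np.unique(np.concatenate([sp, sa]))
    best_tss, best_tau = -np.inf, cands[0]
    for tau in cands:
        sens = (sp >= tau).mean()
        spec = (sa < tau).mean()
        tss = sens + spec - 1
        if tss > best_tss + 1e-15:
            best_tss, best_tau = tss, tau
    return float(best_tss), float(best_tau)


@dataclass
class EnsembleModel:
    """TSS-weighted collection of fitted scorers."""

    members: list = field(default_factory=list)  # (model, tss_weight)

    def __post_init__(self):
        if not self.members:
            raise ValueError("ensemble needs at least one member")
        if all(w == 0 for _, w in self.members):
            raise ValueError("all ensemble weights are zero")
        if any(w < 0 for _, w in self.members):
            raise ValueError("TSS weights must be >= 0")

    def predict(self, env: ScenarioStack) -> pd.Series:
        wsum = sum(w for _, w in self.members)
        acc = np.zeros(len(env.factors))
        for model, w in self.members:
            if w > 0:
                acc += w * model.predict(env.factors)
        return pd.Series(acc / wsum, index=env.factors.index)


def ensemble_project(
    ensemble: EnsembleModel,
    env: ScenarioStack,
    species: str = "",
    tss_threshold: float = 0.0,
) -> SuitabilitySurface:
    """Project the weighted-mean suitability of an ensemble onto a scenario."""
    return SuitabilitySurface(
        species=species,
        scenario=env.scenario,
        values=ensemble.predict(env),
        tss_threshold=tss_threshold,
    )


def clamp(
    surface: SuitabilitySurface,
    env: ScenarioStack,
    limits: dict,
    max_exceed: int = 1,
    penalty: float = 0.0,
) -> SuitabilitySurface:
    """Penalise projection into novel environments.

    A subcatchment where more than ``max_exceed`` factors fall outside the
    training limits has its suitability multiplied by ``penalty`` (default 0:
    a hard clamp).  Exceeding a single factor is tolerated, allowing
    reasonable gap-filling extrapolation while constraining projections to
    environments similar to those the model saw.
    """
    missing = [f for f in limits if f not in env.factors.columns]
    if missing:
        raise ValueError(f"limits name factors absent from scenario: {missing}")
    n_out = pd.Series(0, index=env.factors.index)
    for f, (lo, hi) in limits.items():
        v = env.factors[f]
        n_out = n_out + ((v < lo) | (v > hi)).astype(int)
    vals = surface.values.copy()
    mask = n_out.reindex(vals.index) > max_exceed
    vals[mask] = vals[mask] * penalty
    return surface.copy_with(values=vals)


def binarize(surface: SuitabilitySurface) -> pd.Series:
    """Binary habitat mask: suitable iff suitability >= tau (inclusive)."""
    return surface.values >= surface.tss_threshold


def ensemble_training_limits(ensemble: EnsembleModel) -> dict:
    """Per-factor (min, max) across all member training sets — the envelope
    used for clamping projections."""
    limits: dict = {}
    for model, _ in ensemble.members:
        for f, (lo, hi) in model.training_limits.items():
            if f in limits:
                limits[f] = (min(limits[f][0], lo), max(limits[f][1], hi))
            else:
                limits[f] = (lo, hi)
    return limits


@dataclass
class ReplicateReport:
    replicate: int
    auc: float
    tss: float
    tss_threshold: float


def fit_species_ensemble(
    occ: OccurrenceSet,
    absences: pd.DataFrame,
    env: ScenarioStack,
    n_replicates: int = 5,
    train_fraction: float = 0.7,
    model_kind: str = "gaussian",
    seed: int = 0,
):
    """Replicated 70/30-split fits combined into a TSS-weighted ensemble.

    Each replicate fits one scorer on a random 70% of presences and absences
    and is evaluated on the held-out 30%; its held-out TSS (floored at 0)
    becomes its ensemble weight.  The binary threshold tau is then chosen to
    maximise TSS of the *ensemble* scores over all presence and absence
    localities.

    Returns (EnsembleModel, tau, [ReplicateReport, ...]).
    """
    rng = np.random.default_rng(seed)
    pres = occ.records[["subcatchment", "x", "y"]].reset_index(drop=True)
    absc = absences[["subcatchment", "x", "y"]].reset_index(drop=True)
    members, reports = [], []
    for rep in range(n_replicates):
        pi = rng.permutation(len(pres))
        ai = rng.permutation(len(absc))
        np_tr = max(int(round(train_fraction * len(pres))), 2)
        na_tr = max(int(round(train_fraction * len(absc))), 2)
        p_tr, p_te = pres.iloc[pi[:np_tr]], pres.iloc[pi[np_tr:]]
        a_tr, a_te = absc.iloc[ai[:na_tr]], absc.iloc[ai[na_tr:]]
        if len(p_te) == 0 or len(a_te) == 0:
            p_te, a_te = p_tr, a_tr  # degenerate split on tiny data
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = fit_scorer(p_tr, a_tr, env, model_kind)
        ev = evaluate(model, p_te, a_te, env)
        members.append((model, max(ev.tss, 0.0)))
        reports.append(ReplicateReport(rep, ev.auc, ev.tss, ev.tss_threshold))
    if all(w == 0 for _, w in members):
        # no-skill fallback: equal weights keep the ensemble well defined
        members = [(m, 1.0) for m, _ in members]
    ensemble = EnsembleModel(members)
    sp = ensemble.predict(env).loc[pres["subcatchment"]].to_numpy()
    sa = ensemble.predict(env).loc[absc["subcatchment"]].to_numpy()
    _, tau = max_tss_threshold(sp, sa)
    return ensemble, tau, reports
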