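"""Clinical-marker association and causal analysis against stroke probability.

Given a per-sample clinical table (blood markers, counts, metabolites)
and the CNN ensemble stroke probability, this module provides:

* group comparisons — Mann-Whitney U per marker between predicted
  positive (probability >= 0.40) and negative groups, BH-corrected, with
  markers observed for at most 40 subjects excluded;
* rank correlations — Spearman RCC of each marker with the probability;
* causal inference test (CIT) networks — for ordered triples
  (driver L, mediator M, outcome = probability), an omnibus mediation
  test whose components are (1) L-outcome association, (2) L-M
  association given the outcome, (3) M-outcome association given L, and
  (4) a permutation equivalence test of L independent of the outcome
  given M; the omnibus p is the max of the component p-values, BH-FDR is
  applied across triples, and retained edges are annotated with pairwise
  Pearson correlations;
* the forward-risk incidence ratio between false-positive and
  true-negative follow-up groups, plus the classical 2x2 odds ratio;
* saturation analysis — classifier performance as a function of the
  number of training stroke samples with matched controls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

MIN_SUBJECTS = 40  # a marker enters analysis only if observed for > 40 subjects


@dataclass(frozen=True)
class RiskCounts:
    """Follow-up stroke events: ``a``/``n1`` in the false-positive group,
    ``b``/``n2`` in the true-negative group."""

    n1: int
    a: int
    n2: int
    b: int

    def __post_init__(self) -> None:
        if self.n1 <= 0 or self.n2 <= 0:
            raise ValueError("group sizes must be positive")
        if not (0 <= self.a <= self.n1 and 0 <= self.b <= self.n2):
            raise ValueError("event counts must lie within group sizes")


@dataclass
class CITResult:
    p_assoc: float  # L ~ outcome
    p_lm_given_y: float  # L ~ M | outcome
    p_my_given_l: float  # M ~ outcome | L
    p_independence: float  # equivalence test of L _||_ outcome | M
    p_omnibus: float


@dataclass
class CausalEdge:
    driver: str
    mediator: str
    target: str
    q: float
    p_omnibus: float
    pcc_driver_mediator: float
    pcc_p_driver_mediator: float
    pcc_mediator_target: float
    pcc_p_mediator_target: float
    network: int  # 1 = significant markers as drivers, 2 = as mediators


@dataclass
class CausalNetwork:
    edges: list[CausalEdge]
    n_triples_tested: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "driver": e.driver,
                    "mediator": e.mediator,
                    "target": e.target,
                    "q": e.q,
                    "pcc": e.pcc_driver_mediator,
                    "pcc_p": e.pcc_p_driver_mediator,
                    "pcc_mt": e.pcc_mediator_target,
                    "pcc_mt_p": e.pcc_p_mediator_target,
                    "network": e.network,
                }
                for e in self.edges
            ]
        )

    def to_graphml(self, path: str) -> None:
        import networkx as nx

        g = nx.DiGraph()
        for e in self.edges:
            g.add_edge(e.driver, e.mediator, q=e.q, pcc=e.pcc_driver_mediator)
            g.add_edge(e.mediator, e.target, q=e.q, pcc=e.pcc_mediator_target)
        nx.write_graphml(g, path)


# ---------------------------------------------------------------------------
# Marker screens
# ---------------------------------------------------------------------------

def _eligible_markers(table: pd.DataFrame, min_subjects: int) -> list[str]:
    out = []
    for col in table.columns:
        n_obs = int(table[col].notna().sum())
        if n_obs > min_subjects:
            out.append(col)
        else:
            logger.info("marker %s excluded (%d observations <= %d)", col, n_obs, min_subjects)
    return out


def marker_group_test(
    table: pd.DataFrame,
    final_probabilities: Sequence[float],
    threshold: float = 0.4,
    min_subjects: int = MIN_SUBJECTS,
) -> pd.DataFrame:
    """Mann-Whitney U per marker between predicted positive/negative groups.

    Returns a frame with raw p, direction (+ = higher in the positive
    group) and BH q per eligible marker.
    """
    probs = np.asarray(final_probabilities, dtype=float)
    if len(probs) != len(table):
        raise ValueError("probability vector length must match the table")
    pos = probs >= threshold
    rows = []
    for col in _eligible_markers(table, min_subjects):
        v = table[col].to_numpy(dtype=float)
        ok = np.isfinite(v)
        vp, vn = v[ok & pos], v[ok & ~pos]
        if len(vp) < 2 or len(vn) < 2:
            logger.info("marker %s skipped (a group has < 2 observations)", col)
            continue
        res = stats.mannwhitneyu(vp, vn, alternative="two-sided")
        rows.append(
            {
                "marker": col,
                "p": float(res.pvalue),
                "direction": int(np.sign(np.median(vp) - np.median(vn))),
                "n": int(ok.sum()),
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    return df


def marker_rcc(
    table: pd.DataFrame,
    final_probabilities: Sequence[float],
    min_subjects: int = MIN_SUBJECTS,
) -> pd.DataFrame:
    """Spearman rank correlation of each eligible marker with probability."""
    probs = np.asarray(final_probabilities, dtype=float)
    if len(probs) != len(table):
        raise ValueError("probability vector length must match the table")
    rows = []
    for col in _eligible_markers(table, min_subjects):
        v = table[col].to_numpy(dtype=float)
        ok = np.isfinite(v)
        if ok.sum() < 3 or np.std(v[ok]) == 0:
            logger.info("marker %s skipped (degenerate)", col)
            continue
        rho, p = stats.spearmanr(v[ok], probs[ok])
        rows.append({"marker": col, "rcc": float(rho), "p": float(p), "n": int(ok.sum())})
    df = pd.DataFrame(rows)
    if len(df):
        df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    return df


# ---------------------------------------------------------------------------
# Causal inference test
# ---------------------------------------------------------------------------

def _ols_f_added(y: np.ndarray, X_reduced: np.ndarray, x_new: np.ndarray) -> tuple[float, float]:
    """F test (and p) for adding ``x_new`` to the reduced OLS model of y."""
    n = len(y)
    X0 = np.column_stack([np.ones(n), X_reduced]) if X_reduced is not None else np.ones((n, 1))
    X1 = np.column_stack([X0, x_new])
    b0, res0, *_ = np.linalg.lstsq(X0, y, rcond=None)
    b1, res1, *_ = np.linalg.lstsq(X1, y, rcond=None)
    rss0 = float(res0[0]) if len(res0) else float(((y - X0 @ b0) ** 2).sum())
    rss1 = float(res1[0]) if len(res1) else float(((y - X1 @ b1) ** 2).sum())
    df2 = n - X1.shape[1]
    if df2 <= 0 or rss1 <= 0:
        return 0.0, 1.0
    f = (rss0 - rss1) / (rss1 / df2)
    return f, float(stats.f.sf(f, 1, df2))


def _f_stat_given(y: np.ndarray, covar: np.ndarray, x: np.ndarray) -> float:
    return _ols_f_added(y, covar[:, None], x)[0]


def cit_test(
    driver: np.ndarray,
    mediator: np.ndarray,
    outcome: np.ndarray,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
) -> CITResult:
    """Causal inference test for the triple driver -> mediator -> outcome.

    Components 1-3 are linear-model F tests.  Component 4 tests the
    conditional independence of driver and outcome given the mediator as
    a permutation equivalence test whose null hypothesis is *dependence*:
    surrogate outcomes are built from the fitted outcome-on-driver model
    with permuted residuals, which keeps the direct driver-outcome
    association at its observed strength while destroying any mediation;
    the p-value is the fraction of surrogate conditional F statistics at
    or below the observed one.  Small p4 therefore means the mediator
    absorbs far more of the driver-outcome association than a direct
    effect of that size could explain.  The omnibus p is the max of the
    four components.
    """
    rng = rng or np.random.default_rng()
    L = np.asarray(driver, dtype=float)
    M = np.asarray(mediator, dtype=float)
    Y = np.asarray(outcome, dtype=float)
    if L.std() == 0 or M.std() == 0 or Y.std() == 0:
        raise ValueError("degenerate (constant) variable in triple")
    n = len(Y)

    _, p1 = _ols_f_added(Y, None, L)
    _, p2 = _ols_f_added(M, Y[:, None], L)
    _, p3 = _ols_f_added(Y, L[:, None], M)
    f_obs = _f_stat_given(Y, M, L)
    XL = np.column_stack([np.ones(n), L])
    beta = np.linalg.lstsq(XL, Y, rcond=None)[0]
    yhat = XL @ beta
    resid = Y - yhat
    f_perm = np.empty(n_perm)
    for b in range(n_perm):
        f_perm[b] = _f_stat_given(yhat + resid[rng.permutation(n)], M, L)
    p4 = (1.0 + float((f_perm <= f_obs).sum())) / (n_perm + 1.0)
    return CITResult(
        p_assoc=p1,
        p_lm_given_y=p2,
        p_my_given_l=p3,
        p_independence=p4,
        p_omnibus=max(p1, p2, p3, p4),
    )


def cit_network(
    table: pd.DataFrame,
    final_probabilities: Sequence[float],
    significant_markers: Sequence[str],
    fdr_cut: float = 0.20,
    pcc_alpha: float = 0.05,
    n_perm: int = 1000,
    min_complete: int = 50,
    seed: int = 0,
) -> CausalNetwork:
    """Build the combined two-network causal map onto stroke probability.

    Network 1 uses the significant markers as drivers and the remaining
    markers as mediators; network 2 swaps the roles.  BH-FDR is applied
    across all tested triples; retained edges additionally need pairwise
    Pearson p < ``pcc_alpha`` on both adjacent pairs.
    """
    rng = np.random.default_rng(seed)
    probs = np.asarray(final_probabilities, dtype=float)
    sig = [m for m in significant_markers if m in table.columns]
    rest = [c for c in table.columns if c not in sig]
    candidates = [(d, m, 1) for d in sig for m in rest] + [(d, m, 2) for d in rest for m in sig]

    tested: list[tuple[str, str, int, CITResult]] = []
    for d, m, net in candidates:
        sub = np.column_stack([table[d].to_numpy(float), table[m].to_numpy(float), probs])
        ok = np.isfinite(sub).all(axis=1)
        if ok.sum() < min_complete:
            logger.info("triple (%s, %s) skipped: %d complete cases", d, m, int(ok.sum()))
            continue
        L, M, Y = sub[ok, 0], sub[ok, 1], sub[ok, 2]
        try:
            res = cit_test(L, M, Y, n_perm=n_perm, rng=rng)
        except ValueError:
            logger.info("triple (%s, %s) skipped: degenerate variable", d, m)
            continue
        tested.append((d, m, net, res))

    edges: list[CausalEdge] = []
    if tested:
        qs = multipletests([t[3].p_omnibus for t in tested], method="fdr_bh")[1]
        for (d, m, net, res), q in zip(tested, qs):
            if q >= fdr_cut:
                continue
            sub = np.column_stack([table[d].to_numpy(float), table[m].to_numpy(float), probs])
            ok = np.isfinite(sub).all(axis=1)
            r_dm, p_dm = stats.pearsonr(sub[ok, 0], sub[ok, 1])
            r_mt, p_mt = stats.pearsonr(sub[ok, 1], sub[ok, 2])
            if p_dm >= pcc_alpha or p_mt >= pcc_alpha:
                continue
            edges.append(
                CausalEdge(
                    driver=d,
                    mediator=m,
                    target="stroke_probability",
                    q=float(q),
                    p_omnibus=res.p_omnibus,
                    pcc_driver_mediator=float(r_dm),
                    pcc_p_driver_mediator=float(p_dm),
                    pcc_mediator_target=float(r_mt),
                    pcc_p_mediator_target=float(p_mt),
                    network=net,
                )
            )
    return CausalNetwork(edges=edges, n_triples_tested=len(tested))


# ---------------------------------------------------------------------------
# Forward risk
# ---------------------------------------------------------------------------

def incidence_ratio(counts: RiskCounts) -> float:
    """Incidence-proportion ratio (a/n1)/(b/n2) between the groups.

    This is the quantity the follow-up recall reproduces from its printed
    counts; with zero events in the reference group it returns inf with a
    warning.  See also :func:`odds_ratio` for the classical 2x2 measure.
    """
    if counts.b == 0:
        logger.warning("incidence_ratio: zero events in reference group; returning inf")
        return float("inf")
    return (counts.a / counts.n1) / (counts.b / counts.n2)


def odds_ratio(counts: RiskCounts) -> float:
    """Classical 2x2 odds ratio (a * (n2-b)) / ((n1-a) * b)."""
    denom = (counts.n1 - counts.a) * counts.b
    if denom == 0:
        logger.warning("odds_ratio: degenerate table; returning inf")
        return float("inf")
    return (counts.a * (counts.n2 - counts.b)) / denom


# ---------------------------------------------------------------------------
# Saturation analysis
# ---------------------------------------------------------------------------

def saturation(
    train_samples,
    train_images,
    test_samples,
    test_images,
    sizes: Sequence[int] = (35, 70, 105, 140, 185),
    control_ratio: float = 3.0,
    spec=None,
    config=None,
    seed: int = 0,
) -> pd.DataFrame:
    """Classifier AUC on a fixed independent set vs training stroke count.

    For each size, that many stroke samples plus ``control_ratio`` times as
    many controls are drawn from the training pool, a fresh backbone is
    trained on their augmented replicates, and the AUC is evaluated on the
    held-out independent cohort.
    """
    from strokeface.dataset import STROKE_COPIES, Replicate, flip_image
    from strokeface.model import BackboneSpec, TrainConfig, auc_score, pair_to_array

    spec = spec or BackboneSpec("tiny")
    config = config or TrainConfig.tiny()
    rng = np.random.default_rng(seed)
    strokes = [s for s in train_samples if s.label == "stroke"]
    controls = [s for s in train_samples if s.label == "control"]
    y_test = np.array([1 if s.label == "stroke" else 0 for s in test_samples])
    X_test = {
        s.sample_id: [
            pair_to_array(test_images[s.sample_id], spec.in_channels),
            pair_to_array(flip_image(test_images[s.sample_id]), spec.in_channels),
        ]
        for s in test_samples
    }

    rows = []
    for size in sizes:
        n_ctl = int(round(control_ratio * size))
        if size > len(strokes) or n_ctl > len(controls):
            raise ValueError(f"size {size} exceeds the available training cohort")
        pick = list(rng.choice(len(strokes), size, replace=False))
        pickc = list(rng.choice(len(controls), n_ctl, replace=False))
        chosen = [strokes[i] for i in pick] + [controls[i] for i in pickc]
        X, y = [], []
        for s in chosen:
            copies = STROKE_COPIES if s.label == "stroke" else 1
            pair = train_images[s.sample_id]
            arrays = [pair_to_array(pair, spec.in_channels),
                      pair_to_array(flip_image(pair), spec.in_channels)]
            for _ in range(copies):
                X.extend(arrays)
                y.extend([1 if s.label == "stroke" else 0] * 2)
        model = spec.build(seed=config.seed)
        model.fit(np.stack(X), np.array(y), epochs=config.epochs,
                  learning_rate=config.learning_rate, batch_size=config.batch_size,
                  seed=config.seed)
        preds = np.array(
            [float(model.predict_proba(np.stack(X_test[s.sample_id]))[:, 1].mean())
             for s in test_samples]
        )
        rows.append({"n_stroke": int(size), "n_control": n_ctl,
                     "auc": auc_score(y_test, preds)})
    return pd.DataFrame(rows)
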