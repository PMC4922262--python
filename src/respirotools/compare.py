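"""Repeated-measures comparison of metabolic estimates across methods.

The design is the classic method-comparison layout: each fish is measured
under up to three protocols, so protocol (method) and species are fixed
factors and fish identity a random intercept. The module fits the mixed
model, tests the method x species interaction (dropping it when
non-significant), produces all-pairs method contrasts with a single-step
multivariate-normal multiplicity adjustment, population-level model
predictions per method, and percent differences between methods. A separate
fixed-effects linear model with Tukey-adjusted pairwise species comparisons
and a compact-letter display handles critical swimming speed, which has one
value per fish.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .metrics import MetabolicSummary
from .trace_model import Protocol

__all__ = [
    "ComparisonSpec",
    "ComparisonResult",
    "fit_comparison",
    "percent_difference",
    "fit_ucrit_lm",
    "summaries_to_frame",
]


def summaries_to_frame(records: Sequence[MetabolicSummary]) -> pd.DataFrame:
    """Tidy wide table (one row per fish x method) from summary records."""
    rows = []
    for rec in records:
        rows.append(dict(
            fish_id=rec.fish_id, species=rec.species, swim_mode=rec.swim_mode,
            method=rec.method.value if isinstance(rec.method, Protocol) else rec.method,
            mmr=rec.mmr, smr=rec.smr, aerobic_scope=rec.aerobic_scope,
            ucrit_abs=rec.ucrit_abs_cm_s, ucrit_rel=rec.ucrit_rel_bl_s,
        ))
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ComparisonSpec:
    """What to compare and how.

    ``response`` names the column of the tidy summary table to model.
    ``log_transform`` fits the model on the natural-log scale, in which case
    contrasts are log-ratios and percent differences are computed as
    100*(exp(diff)-1). ``adjustment`` is the multiplicity correction for the
    all-pairs method contrasts ("single-step" multivariate-normal, "holm",
    or "none").
    """

    response: str = "mmr"
    log_transform: bool = False
    alpha: float = 0.05
    adjustment: str = "single-step"
    reml: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.adjustment not in ("single-step", "holm", "none"):
            raise ValueError("adjustment must be 'single-step', 'holm' or 'none'")


@dataclass
class ComparisonResult:
    """Fitted method/species effects, contrasts and model predictions."""

    response: str
    engine: str                       # "mixed" or "ols" (fallback)
    log_scale: bool
    interaction_removed: bool
    interaction_test: Optional[dict]
    fixed_effect_tests: List[dict]
    contrasts: List[dict]
    predictions: pd.DataFrame         # method, pred, se
    species_predictions: pd.DataFrame  # method, species, pred
    n_obs: int
    n_groups: int
    letters: Optional[Dict[str, str]] = None
    notes: List[str] = field(default_factory=list)

    def contrast(self, a: str, b: str) -> dict:
        for c in self.contrasts:
            if c["pair"] == (a, b):
                return c
            if c["pair"] == (b, a):
                flipped = dict(c)
                flipped["pair"] = (a, b)
                flipped["estimate"] = -c["estimate"]
                flipped["z"] = -c["z"]
                flipped["ci_low"], flipped["ci_high"] = -c["ci_high"], -c["ci_low"]
                return flipped
        raise KeyError(f"no contrast for pair ({a}, {b})")


# ---------------------------------------------------------------------------
# design construction (explicit treatment coding; no formula layer)


class _Design:
    """Treatment-coded fixed-effects design for method x species."""

    def __init__(self, methods: List[str], species: List[str], interaction: bool):
        self.methods = methods
        self.species = species
        self.interaction = interaction and len(methods) > 1 and len(species) > 1
        names = ["Intercept"]
        names += [f"method[{m}]" for m in methods[1:]]
        names += [f"species[{s}]" for s in species[1:]]
        if self.interaction:
            names += [f"method[{m}]:species[{s}]"
                      for m in methods[1:] for s in species[1:]]
        self.names = names

    def row(self, method: str, species: str) -> np.ndarray:
        x = [1.0]
        x += [1.0 if method == m else 0.0 for m in self.methods[1:]]
        x += [1.0 if species == s else 0.0 for s in self.species[1:]]
        if self.interaction:
            x += [1.0 if (method == m and species == s) else 0.0
                  for m in self.methods[1:] for s in self.species[1:]]
        return np.array(x)

    def matrix(self, method_col: pd.Series, species_col: pd.Series) -> np.ndarray:
        return np.vstack([self.row(m, s) for m, s in zip(method_col, species_col)])

    def population_row(self, method: str) -> np.ndarray:
        """Design row for a method, averaged over species with equal weight."""
        rows = [self.row(method, s) for s in self.species]
        return np.mean(rows, axis=0)

    def term_indices(self, term: str) -> List[int]:
        if term == "method":
            return [i for i, n in enumerate(self.names)
                    if n.startswith("method[") and ":" not in n]
        if term == "species":
            return [i for i, n in enumerate(self.names)
                    if n.startswith("species[") and ":" not in n]
        if term == "interaction":
            return [i for i, n in enumerate(self.names) if ":" in n]
        raise KeyError(term)


def _wald_f(beta: np.ndarray, cov: np.ndarray, idx: List[int],
            df_den: int) -> Tuple[float, int, int, float]:
    """Wald F test that the coefficients at ``idx`` are jointly zero."""
    L = np.zeros((len(idx), beta.size))
    for r, i in enumerate(idx):
        L[r, i] = 1.0
    est = L @ beta
    v = L @ cov @ L.T
    try:
        w = float(est @ np.linalg.solve(v, est))
    except np.linalg.LinAlgError:
        w = float(est @ np.linalg.pinv(v) @ est)
    q = len(idx)
    f = w / q
    df_den = max(int(df_den), 1)
    p = float(stats.f.sf(f, q, df_den))
    return f, q, df_den, p


def _fit_engine(y: np.ndarray, X: np.ndarray, groups: np.ndarray,
                reml: bool) -> Tuple[np.ndarray, np.ndarray, str, List[str]]:
    """Fit random-intercept model; fall back to OLS when it cannot be fit.

    Returns (beta, cov_beta, engine, notes).
    """
    notes: List[str] = []
    counts = pd.Series(groups).value_counts()
    if (counts > 1).sum() < 2:
        notes.append(
            "fewer than 2 fish with repeated measures: falling back to a "
            "fixed-effects model (no random intercept)"
        )
        res = sm.OLS(y, X).fit()
        return np.asarray(res.params), np.asarray(res.cov_params()), "ols", notes
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = sm.MixedLM(y, X, groups=groups)
            res = model.fit(reml=reml, method=["lbfgs", "bfgs", "cg"])
            beta = np.asarray(res.fe_params)
            cov = np.asarray(res.cov_params())[: beta.size, : beta.size]
            if not (np.all(np.isfinite(beta)) and np.all(np.isfinite(cov))):
                raise ValueError("non-finite mixed-model estimates")
            return beta, cov, "mixed", notes
        except Exception as exc:  # degenerate data (e.g. zero variance)
            notes.append(f"mixed model fit failed ({exc}); using OLS fallback")
            res = sm.OLS(y, X).fit()
            return np.asarray(res.params), np.asarray(res.cov_params()), "ols", notes


def _max_abs_z_sf(zvals: np.ndarray, V: np.ndarray, n_draws: int = 100_000,
                  seed: int = 20160323) -> np.ndarray:
    """Single-step adjusted p-values: P(max_j |Z_j| >= |z_i|).

    The contrast covariance is typically singular (k pairwise contrasts from
    k-1 free coefficients), so the joint distribution is sampled through a
    rank-revealing factor with a fixed quasi-random seed.
    """
    d = np.sqrt(np.clip(np.diag(V), 1e-300, None))
    R = V / np.outer(d, d)
    evals, evecs = np.linalg.eigh((R + R.T) / 2.0)
    keep = evals > 1e-10
    A = evecs[:, keep] * np.sqrt(evals[keep])
    rng = np.random.default_rng(seed)
    G = rng.standard_normal((n_draws, int(keep.sum())))
    maxabs = np.abs(G @ A.T).max(axis=1)
    return np.array([float(np.mean(maxabs >= abs(z))) for z in zvals])


def _adjust(zvals: np.ndarray, raw_p: np.ndarray, V: np.ndarray,
            method: str) -> np.ndarray:
    if method == "none":
        return raw_p
    if method == "holm":
        order = np.argsort(-np.abs(zvals))
        k = len(zvals)
        adj = np.empty(k)
        running = 0.0
        for rank, i in enumerate(order):
            p = min((k - rank) * raw_p[i], 1.0)
            running = max(running, p)
            adj[i] = running
        return adj
    return np.minimum(_max_abs_z_sf(zvals, V), 1.0)


def fit_comparison(data: pd.DataFrame, spec: ComparisonSpec) -> ComparisonResult:
    """Fit the repeated-measures method/species comparison.

    ``data`` is a tidy table with columns ``fish_id``, ``species``,
    ``method`` and the response named by ``spec.response``; rows with a
    missing response are dropped (fish need not complete every method).
    The method x species interaction is tested first and removed when
    non-significant at ``spec.alpha``.
    """
    required = {"fish_id", "species", "method", spec.response}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"comparison table missing column(s) {sorted(missing)}")
    df = data.dropna(subset=[spec.response]).copy()
    methods = sorted(df["method"].astype(str).unique())
    species = sorted(df["species"].astype(str).unique())
    if len(methods) < 2:
        raise ValueError("need at least 2 methods to compare")
    y = df[spec.response].to_numpy(dtype=float)
    if spec.log_transform:
        if np.any(y <= 0):
            raise ValueError("log transform requires strictly positive responses")
        y = np.log(y)
    groups = df["fish_id"].astype(str).to_numpy()
    n_groups = len(np.unique(groups))

    notes: List[str] = []
    interaction_test = None
    interaction_removed = False
    design = _Design(methods, species, interaction=True)
    if design.interaction:
        X = design.matrix(df["method"].astype(str), df["species"].astype(str))
        beta, cov, engine, fit_notes = _fit_engine(y, X, groups, spec.reml)
        notes += fit_notes
        df_den = max(len(y) - X.shape[1] - (n_groups - 1 if engine == "mixed" else 0), 1)
        f, q, dd, p = _wald_f(beta, cov, design.term_indices("interaction"), df_den)
        interaction_test = dict(term="method:species", F=f, df_num=q, df_den=dd, p=p)
        if p >= spec.alpha:
            interaction_removed = True
            design = _Design(methods, species, interaction=False)
    else:
        design = _Design(methods, species, interaction=False)

    X = design.matrix(df["method"].astype(str), df["species"].astype(str))
    beta, cov, engine, fit_notes = _fit_engine(y, X, groups, spec.reml)
    notes += fit_notes
    df_den = max(len(y) - X.shape[1] - (n_groups - 1 if engine == "mixed" else 0), 1)

    fixed_effect_tests = []
    for term in ("method", "species") if len(species) > 1 else ("method",):
        idx = design.term_indices(term)
        if not idx:
            continue
        f, q, dd, p = _wald_f(beta, cov, idx, df_den)
        fixed_effect_tests.append(dict(term=term, F=f, df_num=q, df_den=dd, p=p))
    if interaction_test is not None and not interaction_removed:
        fixed_effect_tests.append(interaction_test)

    # population-level predictions (species-balanced)
    pred_rows = []
    pop_rows = {}
    for m in methods:
        x = design.population_row(m)
        pop_rows[m] = x
        se = float(np.sqrt(max(x @ cov @ x, 0.0)))
        pred_rows.append(dict(method=m, pred=float(x @ beta), se=se))
    predictions = pd.DataFrame(pred_rows)

    sp_rows = []
    for m in methods:
        for s in species:
            x = design.row(m, s)
            sp_rows.append(dict(method=m, species=s, pred=float(x @ beta)))
    species_predictions = pd.DataFrame(sp_rows)

    # all-pairs method contrasts
    pairs = [(methods[i], methods[j])
             for i in range(len(methods)) for j in range(i + 1, len(methods))]
    L = np.vstack([pop_rows[a] - pop_rows[b] for a, b in pairs])
    est = L @ beta
    V = L @ cov @ L.T
    se = np.sqrt(np.clip(np.diag(V), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, est / se, 0.0)
    raw_p = 2.0 * stats.norm.sf(np.abs(z))
    adj_p = _adjust(z, raw_p, V, spec.adjustment)
    zcrit = stats.norm.ppf(1 - spec.alpha / 2)
    contrasts = [
        dict(pair=pair, estimate=float(e), se=float(s_), z=float(z_),
             p=float(rp), p_adj=float(ap),
             ci_low=float(e - zcrit * s_), ci_high=float(e + zcrit * s_))
        for pair, e, s_, z_, rp, ap in zip(pairs, est, se, z, raw_p, adj_p)
    ]

    return ComparisonResult(
        response=spec.response, engine=engine, log_scale=spec.log_transform,
        interaction_removed=interaction_removed, interaction_test=interaction_test,
        fixed_effect_tests=fixed_effect_tests, contrasts=contrasts,
        predictions=predictions, species_predictions=species_predictions,
        n_obs=len(y), n_groups=n_groups, notes=notes,
    )


def percent_difference(result: ComparisonResult,
                       pair: Tuple[str, str]) -> Tuple[float, Tuple[float, float]]:
    """Model-predicted percent difference of method A relative to method B.

    Returns (overall percent, per-species (min, max) range). On the raw
    scale this is 100*(pred_A - pred_B)/pred_B; on the log scale,
    100*(exp(pred_A - pred_B) - 1).
    """
    a, b = pair
    preds = result.predictions.set_index("method")["pred"]
    if a not in preds.index or b not in preds.index:
        raise KeyError(f"methods {pair} not found in predictions")

    def pct(pa: float, pb: float) -> float:
        if result.log_scale:
            return 100.0 * (math.exp(pa - pb) - 1.0)
        if pb <= 0:
            raise ValueError("reference prediction must be positive")
        return 100.0 * (pa - pb) / pb

    overall = pct(float(preds[a]), float(preds[b]))
    sp = result.species_predictions.pivot(index="species", columns="method",
                                          values="pred")
    per_species = [pct(float(row[a]), float(row[b])) for _, row in sp.iterrows()]
    return overall, (min(per_species), max(per_species))


# ---------------------------------------------------------------------------
# Ucrit linear model (one value per fish)


def _compact_letter_display(levels: List[str], means: Dict[str, float],
                            nonsig_pairs: set) -> Dict[str, str]:
    """Letters from maximal cliques of the non-significant-pair graph.

    Two levels share a letter iff they are not significantly different.
    """
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(levels)
    g.add_edges_from(nonsig_pairs)
    cliques = list(nx.find_cliques(g))
    cliques.sort(key=lambda c: -np.mean([means[x] for x in c]))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters: Dict[str, List[str]] = {lv: [] for lv in levels}
    for i, clique in enumerate(cliques):
        for lv in clique:
            letters[lv].append(alphabet[i % len(alphabet)])
    return {lv: "".join(sorted(set(ls))) for lv, ls in letters.items()}


def fit_ucrit_lm(data: pd.DataFrame, response: str = "ucrit_abs",
                 alpha: float = 0.05) -> ComparisonResult:
    """Linear model of critical swimming speed on swim mode and species.

    Species are nested within swim mode, so the sums of squares are
    partitioned sequentially: mode first, then species-within-mode, with
    the residual from the full species model. Pairwise species comparisons
    use Tukey's HSD and are summarised as a compact letter display
    (levels sharing a letter do not differ significantly).
    """
    required = {"fish_id", "species", "swim_mode", response}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"Ucrit table missing column(s) {sorted(missing)}")
    df = data.dropna(subset=[response]).copy()
    if df["fish_id"].duplicated().any():
        raise ValueError("expected one Ucrit value per fish")
    species = sorted(df["species"].astype(str).unique())
    modes = sorted(df["swim_mode"].astype(str).unique())
    if len(species) < 2:
        raise ValueError("need at least 2 groups for the Ucrit linear model")
    y = df[response].to_numpy(dtype=float)
    n = len(y)
    grand = y.mean()
    ss_mode = sum(
        len(sub) * (sub[response].mean() - grand) ** 2
        for _, sub in df.groupby("swim_mode")
    )
    ss_species = sum(
        len(sub) * (sub[response].mean() - grand) ** 2
        for _, sub in df.groupby("species")
    )
    sse = sum(
        ((sub[response] - sub[response].mean()) ** 2).sum()
        for _, sub in df.groupby("species")
    )
    df_mode = len(modes) - 1
    df_sp = len(species) - len(modes)
    df_res = n - len(species)
    if df_res < 1:
        raise ValueError("no residual degrees of freedom for the Ucrit model")
    mse = sse / df_res
    tests = []
    if df_mode >= 1:
        f = (ss_mode / df_mode) / mse if mse > 0 else float("inf")
        tests.append(dict(term="swim_mode", F=float(f), df_num=df_mode,
                          df_den=df_res, p=float(stats.f.sf(f, df_mode, df_res))))
    if df_sp >= 1:
        ss_within = max(ss_species - ss_mode, 0.0)
        f = (ss_within / df_sp) / mse if mse > 0 else float("inf")
        tests.append(dict(term="species(within mode)", F=float(f), df_num=df_sp,
                          df_den=df_res, p=float(stats.f.sf(f, df_sp, df_res))))

    means = {s: float(df.loc[df["species"] == s, response].mean()) for s in species}
    nonsig = set()
    contrasts = []
    if mse > 0:
        tk = pairwise_tukeyhsd(y, df["species"].astype(str).to_numpy(), alpha=alpha)
        frame = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
        for _, row in frame.iterrows():
            pair = (str(row["group1"]), str(row["group2"]))
            contrasts.append(dict(pair=pair, estimate=float(row["meandiff"]),
                                  se=float("nan"), z=float("nan"),
                                  p=float(row["p-adj"]), p_adj=float(row["p-adj"]),
                                  ci_low=float(row["lower"]),
                                  ci_high=float(row["upper"])))
            if not bool(row["reject"]):
                nonsig.add(pair)
    else:
        # degenerate zero-variance data: nothing is distinguishable
        for i in range(len(species)):
            for j in range(i + 1, len(species)):
                pair = (species[i], species[j])
                contrasts.append(dict(pair=pair, estimate=means[pair[1]] - means[pair[0]],
                                      se=0.0, z=float("nan"), p=1.0, p_adj=1.0,
                                      ci_low=0.0, ci_high=0.0))
                nonsig.add(pair)
        tests = [dict(term="swim_mode", F=0.0, df_num=max(df_mode, 1),
                      df_den=df_res, p=1.0)]
    letters = _compact_letter_display(species, means, nonsig)

    mode_means = df.groupby("swim_mode")[response].mean()
    predictions = pd.DataFrame(
        [dict(method=m, pred=float(mode_means[m]), se=float("nan")) for m in modes]
    )
    species_predictions = pd.DataFrame(
        [dict(method=str(df.loc[df["species"] == s, "swim_mode"].iloc[0]),
              species=s, pred=means[s]) for s in species]
    )
    return ComparisonResult(
        response=response, engine="ols", log_scale=False,
        interaction_removed=False, interaction_test=None,
        fixed_effect_tests=tests, contrasts=contrasts,
        predictions=predictions, species_predictions=species_predictions,
        n_obs=n, n_groups=n, letters=letters,
    )
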