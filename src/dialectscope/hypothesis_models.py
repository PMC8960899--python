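"""Mate-choice hypothesis matrices, mixtures, repeatability, and the
dyad-level distance model with crossed random effects.

Pair types are two-letter lineage codes over {D, W}: first letter genetic
origin, second letter rearing culture.  Hypotheses are indicator masks over
the 16 (female type x male type) cells:

* H1  — innate preference for a genetic trait: genetic letters match.
* H2  — mutual imprinting on parental morphotype: each partner's genetic
        letter equals the other's rearing letter.
* H3  — learnt preference for the rearing culture: rearing letters match.
* H1W — mixed-genetic-origin dyads (one W-origin, one D-origin member);
        the direction-specific variant (W female x D male) is available.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .synthetic_data.types import BirdRecord

PAIR_TYPES = ("DD", "DW", "WD", "WW")


@dataclass
class PairTypeMatrix:
    """4x4 nonnegative counts indexed (female type, male type)."""

    cells: np.ndarray

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=float)
        if self.cells.shape != (4, 4):
            raise ValueError("PairTypeMatrix must be 4x4")
        if np.any(self.cells < 0):
            raise ValueError("cells must be non-negative")

    @property
    def total(self) -> float:
        return float(self.cells.sum())

    def flat(self) -> np.ndarray:
        return self.cells.ravel()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.cells, index=list(PAIR_TYPES), columns=list(PAIR_TYPES))


@dataclass
class HypothesisSpec:
    name: str
    mask: np.ndarray  # 4x4 boolean, rows = female type, cols = male type


def _mask(rule) -> np.ndarray:
    return np.array([[bool(rule(f, m)) for m in PAIR_TYPES] for f in PAIR_TYPES])


def hypothesis(name: str, *, directional_h1w: bool = False) -> HypothesisSpec:
    """Build one of the named hypothesis masks (H1, H2, H3, H1W)."""
    rules = {
        "H1": lambda f, m: f[0] == m[0],
        "H2": lambda f, m: m[0] == f[1] and f[0] == m[1],
        "H3": lambda f, m: f[1] == m[1],
        "H1W": (
            (lambda f, m: f[0] == "W" and m[0] == "D")
            if directional_h1w
            else (lambda f, m: f[0] != m[0])
        ),
    }
    if name not in rules:
        raise ValueError(f"unknown hypothesis {name!r}")
    return HypothesisSpec(name=name, mask=_mask(rules[name]))


@dataclass
class MixtureWeights:
    weights: dict[str, float]
    achieved_correlation: float


def expected_matrix(
    hyp: HypothesisSpec,
    composition: dict[str, dict[str, int]],
    total_pairs: float,
) -> PairTypeMatrix:
    """Distribute ``total_pairs`` over allowed cells proportionally to the
    product of available female and male counts per cell.

    ``composition`` maps sex ('F'/'M') to {pair type: count}.
    """
    f = np.array([composition["F"].get(t, 0) for t in PAIR_TYPES], dtype=float)
    m = np.array([composition["M"].get(t, 0) for t in PAIR_TYPES], dtype=float)
    weights = np.outer(f, m) * hyp.mask
    s = weights.sum()
    if s <= 0:
        raise ValueError(f"no allowed cell of {hyp.name} has members")
    return PairTypeMatrix(cells=total_pairs * weights / s)


def observed_matrix(
    pairs: list[tuple[str, str]],
    birds: list[BirdRecord],
) -> PairTypeMatrix:
    """Count observed pairs into the 16 (female type, male type) cells."""
    code = {b.bird_id: b.lineage_code[:2] for b in birds}
    idx = {t: i for i, t in enumerate(PAIR_TYPES)}
    cells = np.zeros((4, 4))
    for f, m in pairs:
        try:
            cells[idx[code[f]], idx[code[m]]] += 1
        except KeyError as err:
            raise ValueError(f"unknown lineage code for pair member {err}") from err
    return PairTypeMatrix(cells=cells)


def matrix_correlation(a: PairTypeMatrix, b: PairTypeMatrix) -> tuple[float, float]:
    """Pearson r over the 16 flattened cells, with the two-tailed p from the
    t-transform at df = 14."""
    x, y = a.flat(), b.flat()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("matrix correlation undefined for a constant matrix")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def fit_mixture(
    observed: PairTypeMatrix,
    hypotheses: list[HypothesisSpec],
    composition: dict[str, dict[str, int]],
    grid_step: float = 0.01,
) -> MixtureWeights:
    """Simplex grid search over hypothesis mixture weights maximising the
    correlation between the mixed expected matrix and the observed one.

    Ties resolve toward sparser weight vectors.
    """
    if not 0 < grid_step <= 0.5:
        raise ValueError("grid_step must lie in (0, 0.5]")
    if len(hypotheses) < 1:
        raise ValueError("need at least one hypothesis")
    total = observed.total if observed.total > 0 else 1.0
    E = np.vstack(
        [expected_matrix(h, composition, total).flat() for h in hypotheses]
    )
    names = [h.name for h in hypotheses]
    steps = int(round(1.0 / grid_step))
    h = len(hypotheses)
    if h == 1:
        r, _ = matrix_correlation(PairTypeMatrix(E[0].reshape(4, 4)), observed)
        return MixtureWeights(weights={names[0]: 1.0}, achieved_correlation=r)
    combos = np.array(
        [c for c in itertools.product(range(steps + 1), repeat=h - 1) if sum(c) <= steps]
    )
    W = np.column_stack([combos, steps - combos.sum(axis=1)]) / steps
    M = W @ E
    o = observed.flat()
    oc = o - o.mean()
    Mc = M - M.mean(axis=1, keepdims=True)
    denom = np.sqrt((Mc**2).sum(axis=1)) * np.sqrt((oc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (Mc @ oc) / denom
    corr = np.where(np.isfinite(corr), corr, -np.inf)
    best_r = corr.max()
    tied = np.flatnonzero(corr >= best_r - 1e-12)
    sparsity = (W[tied] > 1e-12).sum(axis=1)
    pick = tied[np.argmin(sparsity)]
    return MixtureWeights(
        weights={n: float(w) for n, w in zip(names, W[pick])},
        achieved_correlation=float(corr[pick]),
    )


def replicate_repeatability(
    rep1: PairTypeMatrix, rep2: PairTypeMatrix
) -> tuple[float, float, np.ndarray]:
    """Pearson r between two replicate matrices over the 16 cells; also
    returns the mask of song-assortative (rearing-matched) cells."""
    r, p = matrix_correlation(rep1, rep2)
    return r, p, hypothesis("H3").mask


# ---------------------------------------------------------------------------
# dyad-level distance model


@dataclass
class DistanceModelFit:
    fixed: pd.DataFrame  # index = term; estimate, ci_low, ci_high, t, p
    variance_shares: dict[str, float]  # percent, sums to 100
    converged: bool
    n_obs: int
    singular: bool = False


def dyad_predictors(
    dyads: list[tuple[str, str]],
    birds: list[BirdRecord],
    ml_peers: dict[tuple[str, str], float],
    sap_peers: dict[tuple[str, str], float],
    *,
    ml_parents: dict[tuple[str, str], float] | None = None,
    sap_parents: dict[tuple[str, str], float] | None = None,
    sap_foster: dict[tuple[str, str], float] | None = None,
    directional_h1w: bool = False,
) -> pd.DataFrame:
    """Per-dyad predictor table for the distance model.

    Similarity lookups are keyed by (male_id, female_rearing_aviary).
    Indicator codings put the 'match' level at 1 (predicted to reduce
    distance, i.e. a negative model coefficient); continuous covariates are
    z-scored; the absolute male-female body-size difference is included.
    """
    by_id = {b.bird_id: b for b in birds}
    masks = {n: hypothesis(n, directional_h1w=directional_h1w).mask for n in ("H1W", "H2", "H3")}
    idx = {t: i for i, t in enumerate(PAIR_TYPES)}
    rows = []
    for f, m in dyads:
        bf, bm = by_id[f], by_id[m]
        fi, mi = idx[bf.lineage_code[:2]], idx[bm.lineage_code[:2]]
        key = (m, bf.rearing_aviary)
        if key not in ml_peers or key not in sap_peers:
            raise ValueError(f"missing similarity score for dyad ({f}, {m})")
        row = {
            "female_id": f,
            "male_id": m,
            "h1w": float(masks["H1W"][fi, mi]),
            "h2": float(masks["H2"][fi, mi]),
            "h3": float(masks["H3"][fi, mi]),
            "size_diff": abs(bf.body_size - bm.body_size),
            "ml_peers": ml_peers[key],
            "sap_peers": sap_peers[key],
            "aviary_pair": f"{bf.rearing_aviary}|{bm.rearing_aviary}",
        }
        for name, table in (
            ("ml_parents", ml_parents),
            ("sap_parents", sap_parents),
            ("sap_foster", sap_foster),
        ):
            if table is not None:
                row[name] = table[key]
        rows.append(row)
    df = pd.DataFrame(rows)
    for col in df.columns:
        if col in ("female_id", "male_id", "aviary_pair", "h1w", "h2", "h3"):
            continue
        sd = df[col].std(ddof=0)
        if sd < 1e-12:
            raise ValueError(f"degenerate predictor {col!r}: zero variance")
        df[col] = (df[col] - df[col].mean()) / sd
    return df


def predictor_correlations(predictors: pd.DataFrame) -> pd.DataFrame:
    num = predictors.drop(columns=["female_id", "male_id", "aviary_pair"])
    return num.corr()


def fit_distance_model(
    dyad_day: pd.DataFrame,
    predictors: pd.DataFrame,
    fixed_effects: list[str] | None = None,
    *,
    response: str = "ln_distance",
    standardize_response: bool = True,
) -> DistanceModelFit:
    """Linear mixed model for daily dyad distances.

    Response: ln distance (centred and scaled by default).  Random
    intercepts: pair, male, female and rearing-aviary pair, fitted as
    variance components by REML; fixed-effect CIs and p-values use the
    normal approximation.
    """
    if fixed_effects is None:
        fixed_effects = ["h1w", "h2", "h3", "ml_peers", "sap_peers"]
    df = dyad_day.rename(columns={"bird_a": "female_id", "bird_b": "male_id"}).merge(
        predictors, on=["female_id", "male_id"], how="inner"
    )
    if df.empty:
        raise ValueError("no dyad-days after joining predictors")
    if not np.all(np.isfinite(df[response])):
        raise ValueError("non-finite response values")
    y = df[response].to_numpy(dtype=float)
    if standardize_response:
        y = (y - y.mean()) / y.std(ddof=0)
    df = df.assign(_resp=y, _grp=1, pair_id=df["female_id"] + "|" + df["male_id"])
    vc = {
        "pair": "0 + C(pair_id)",
        "male": "0 + C(male_id)",
        "female": "0 + C(female_id)",
        "aviary_pair": "0 + C(aviary_pair)",
    }
    formula = "_resp ~ " + " + ".join(fixed_effects)
    model = sm.MixedLM.from_formula(
        formula, groups="_grp", vc_formula=vc, re_formula="0", data=df
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(reml=True, method="lbfgs")
    vcomp = {name: float(v) for name, v in zip(model.exog_vc.names, result.vcomp)}
    resid = float(result.scale)
    total = sum(vcomp.values()) + resid
    shares = {k: 100.0 * v / total for k, v in vcomp.items()}
    shares["residual"] = 100.0 * resid / total
    singular = any(v / total < 1e-10 for v in vcomp.values())
    if singular:
        warnings.warn("singular fit: a variance component is at the zero boundary",
                      stacklevel=2)
    terms = ["Intercept"] + fixed_effects
    ci = result.conf_int()
    fixed = pd.DataFrame(
        {
            "estimate": [result.params[t] for t in terms],
            "ci_low": [ci.loc[t, 0] for t in terms],
            "ci_high": [ci.loc[t, 1] for t in terms],
            "t": [result.tvalues[t] for t in terms],
            "p": [result.pvalues[t] for t in terms],
        },
        index=terms,
    )
    return DistanceModelFit(
        fixed=fixed,
        variance_shares=shares,
        converged=bool(result.converged),
        n_obs=int(len(df)),
        singular=singular,
    )
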