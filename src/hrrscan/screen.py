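"""CRISPRi screen analysis: QC, control-based normalization, and enhancer-level
robust rank aggregation (RRA).

The analysis follows the screen's published recipe: the 1% lowest-count
guides of each sample are removed, per-sample size factors are estimated by
median-of-ratios over the non-targeting controls only, guide log2 fold
changes are computed between timepoints, and enhancer-level enrichment is
scored by the alpha-RRA statistic (minimum Beta order-statistic probability
over the guides ranking inside the top alpha fraction) with a label-
permutation null and Benjamini-Hochberg FDR. Enhancers at q < 0.05 are the
screen hits. Positive and negative selection are separate analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CountMatrix",
    "RraResult",
    "remove_low_count",
    "control_size_factors",
    "guide_lfc",
    "rra_rho",
    "rra_enhancer",
    "run_screen",
]


@dataclass
class CountMatrix:
    """Guide x sample counts with sample metadata.

    ``counts``: DataFrame indexed by guide id, one column per sample.
    ``samples``: DataFrame indexed by sample id with ``timepoint`` (day0 /
    day7 / day21) and ``replicate`` columns. ``membership`` maps targeting
    guide ids to enhancer ids; control guides map to None.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    membership: dict[str, str | None]

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("guide ids must be unique")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.index) - set(self.membership)
        if missing:
            raise ValueError(f"guides without membership: {sorted(missing)[:5]}")
        if not any(v is None for v in self.membership.values()):
            raise ValueError("at least one control guide is required")

    @property
    def control_ids(self) -> list[str]:
        return [g for g in self.counts.index if self.membership[g] is None]

    @property
    def targeting_ids(self) -> list[str]:
        return [g for g in self.counts.index if self.membership[g] is not None]


def remove_low_count(
    cm: CountMatrix, fraction: float = 0.01
) -> tuple[CountMatrix, list[str]]:
    """Drop, from every sample, the guides in any sample's lowest ``fraction``.

    Per sample, the ceil(fraction * n) lowest-count guides are flagged, with
    all guides tied at the cutoff value flagged too; a guide flagged in ANY
    sample is removed globally so every sample shares one guide universe.
    Returns the filtered matrix and the dropped guide ids.
    """
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    if fraction == 0:
        return cm, []
    n = cm.counts.shape[0]
    k = math.ceil(fraction * n)
    flagged: set[str] = set()
    for col in cm.counts.columns:
        vals = cm.counts[col].sort_values(kind="mergesort")
        cutoff = vals.iloc[k - 1]
        flagged |= set(cm.counts.index[cm.counts[col] <= cutoff])
    keep = [g for g in cm.counts.index if g not in flagged]
    if not keep:
        raise ValueError("low-count filter removed every guide")
    return (
        CountMatrix(
            cm.counts.loc[keep],
            cm.samples,
            {g: cm.membership[g] for g in keep},
        ),
        sorted(flagged),
    )


def control_size_factors(cm: CountMatrix) -> pd.Series:
    """DESeq-style median-of-ratios size factors from control guides only.

    Controls with a zero count in any sample are excluded from the factor
    computation. factor_s = median over controls g of
    count_{g,s} / geomean_{s'}(count_{g,s'}).
    """
    ctrl = cm.counts.loc[cm.control_ids]
    ctrl = ctrl[(ctrl > 0).all(axis=1)]
    if len(ctrl) < 1:
        raise ValueError("no control guide has all-positive counts")
    log_geo = np.log(ctrl).mean(axis=1)
    ratios = np.exp(np.log(ctrl).sub(log_geo, axis=0))
    return ratios.median(axis=0)


def normalize(cm: CountMatrix, factors: pd.Series | None = None) -> pd.DataFrame:
    if factors is None:
        factors = control_size_factors(cm)
    return cm.counts.div(factors, axis=1)


def guide_lfc(
    norm: pd.DataFrame,
    samples: pd.DataFrame,
    t_from: str = "day0",
    t_to: str = "day21",
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-guide log2 fold change between timepoints, paired by replicate.

    Returns a DataFrame with one ``lfc_rep<r>`` column per replicate pair
    and a ``score`` column holding the mean across replicates.
    """
    reps_from = samples[samples["timepoint"] == t_from]
    reps_to = samples[samples["timepoint"] == t_to]
    pairs = []
    for rep in sorted(reps_from["replicate"].unique()):
        a = reps_from[reps_from["replicate"] == rep]
        b = reps_to[reps_to["replicate"] == rep]
        if len(a) != 1 or len(b) != 1:
            raise ValueError(f"replicate {rep!r} lacks a {t_from}/{t_to} pairing")
        pairs.append((rep, a.index[0], b.index[0]))
    if not pairs:
        raise ValueError(f"no replicate pairs between {t_from} and {t_to}")
    out = pd.DataFrame(index=norm.index)
    for rep, s_from, s_to in pairs:
        out[f"lfc_rep{rep}"] = np.log2(
            (norm[s_to] + pseudocount) / (norm[s_from] + pseudocount)
        )
    out["score"] = out.mean(axis=1)
    return out


@dataclass
class RraResult:
    enhancer_id: str
    direction: str
    m: int  # guides used
    j: int  # guides passing alpha
    rho: float
    p: float
    q: float = float("nan")

    @property
    def significant(self) -> bool:
        return self.q < 0.05


def rra_rho(u_sorted: np.ndarray, alpha: float) -> tuple[float, int]:
    """alpha-RRA statistic for one set of sorted normalized ranks.

    rho = min over the j ranks with u <= alpha of P(Beta(k, m-k+1) <= u_(k));
    rho = 1 when no rank passes alpha.
    """
    m = len(u_sorted)
    j = int(np.searchsorted(u_sorted, alpha, side="right"))
    if j == 0:
        return 1.0, 0
    k = np.arange(1, j + 1)
    probs = stats.beta.cdf(u_sorted[:j], k, m - k + 1)
    return float(probs.min()), j


def _normalized_ranks(scores: pd.Series, direction: str) -> pd.Series:
    """Mid-rank normalized ranks in (0, 1]; best-selected guides rank lowest."""
    if direction == "positive":
        ranked = (-scores).rank(method="average")
    elif direction == "negative":
        ranked = scores.rank(method="average")
    else:
        raise ValueError("direction must be 'positive' or 'negative'")
    return ranked / len(scores)


def rra_enhancer(
    scores: pd.Series,
    membership: dict[str, str | None],
    direction: str = "positive",
    alpha: float = 0.25,
    n_perm: int = 10_000,
    seed: int = 0,
    exact: bool = False,
) -> list[RraResult]:
    """Enhancer-level alpha-RRA with matched-size label permutation null.

    ``scores`` covers all ranked guides (controls included: they shape the
    ranking but belong to no enhancer). Guide ranks are normalized to (0, 1];
    per enhancer, rho aggregates the Beta order-statistic probabilities of
    its guides' ranks. The null permutes guide->enhancer labels over the
    pool of all targeting guides, preserving each enhancer's guide count;
    p uses the add-one estimator so p >= 1/(1+n_perm). With ``exact=True``
    the null is enumerated exhaustively per enhancer (all C(N, m) subsets of
    the targeting-guide ranks) and p is the exact null probability. BH
    correction runs across testable enhancers within the direction.
    Enhancers with zero scored guides are excluded.
    """
    u = _normalized_ranks(scores, direction)
    enh_guides: dict[str, list[str]] = {}
    targeting: list[str] = []
    for g in scores.index:
        e = membership.get(g)
        if e is not None:
            targeting.append(g)
            enh_guides.setdefault(e, []).append(g)
    results: list[RraResult] = []
    testable: list[tuple[str, np.ndarray]] = []
    for e, gs in sorted(enh_guides.items()):
        uu = np.sort(u.loc[gs].to_numpy())
        testable.append((e, uu))
    if not testable:
        return []
    sizes = [len(uu) for _, uu in testable]
    obs = [rra_rho(uu, alpha) for _, uu in testable]
    pool = u.loc[targeting].to_numpy()
    if exact:
        from itertools import combinations

        pvals = np.empty(len(testable))
        for i, m in enumerate(sizes):
            hits = total = 0
            for subset in combinations(pool, m):
                rho_p, _ = rra_rho(np.sort(np.array(subset)), alpha)
                total += 1
                if rho_p <= obs[i][0]:
                    hits += 1
            pvals[i] = hits / total
    else:
        rng = np.random.default_rng(seed)
        exceed = np.zeros(len(testable), dtype=int)
        offsets = np.cumsum([0] + sizes)
        if offsets[-1] > len(pool):
            raise ValueError("more enhancer guide slots than targeting guides")
        by_size: dict[int, np.ndarray] = {}
        for i, m in enumerate(sizes):
            by_size.setdefault(m, [])
            by_size[m].append(i)
        by_size = {m: np.asarray(v) for m, v in by_size.items()}
        obs_rho = np.array([o[0] for o in obs])
        for _ in range(n_perm):
            perm = rng.permutation(pool)
            for m, idxs in by_size.items():
                blocks = np.sort(
                    np.stack([perm[offsets[i] : offsets[i + 1]] for i in idxs]),
                    axis=1,
                )
                k = np.arange(1, m + 1)
                probs = np.where(
                    blocks <= alpha, stats.beta.cdf(blocks, k, m - k + 1), 1.0
                )
                exceed[idxs] += probs.min(axis=1) <= obs_rho[idxs]
        pvals = (1 + exceed) / (1 + n_perm)
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    for (e, uu), (rho, j), p, q in zip(testable, obs, pvals, qvals):
        results.append(
            RraResult(e, direction, len(uu), j, rho, float(p), float(q))
        )
    return results


def run_screen(
    cm: CountMatrix,
    direction: str = "positive",
    t_from: str = "day0",
    t_to: str = "day21",
    low_count_fraction: float = 0.01,
    alpha: float = 0.25,
    n_perm: int = 10_000,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[RraResult]]:
    """Full screen analysis: QC -> normalize -> LFC -> enhancer RRA."""
    filtered, _dropped = remove_low_count(cm, low_count_fraction)
    norm = normalize(filtered)
    lfc = guide_lfc(norm, filtered.samples, t_from, t_to)
    results = rra_enhancer(
        lfc["score"], filtered.membership, direction, alpha, n_perm, seed
    )
    return lfc, results


def read_count_table(path: str, has_enhancer_col: bool = True) -> tuple[pd.DataFrame, dict[str, str | None]]:
    """Read a screen count TSV (guide id, optional enhancer id, samples...)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    membership: dict[str, str | None] = {}
    if has_enhancer_col:
        enh = df.iloc[:, 0]
        df = df.iloc[:, 1:]
        for g, e in enh.items():
            membership[g] = None if (pd.isna(e) or e in ("NT", "")) else str(e)
    else:
        membership = {g: None for g in df.index}
    return df.astype(int), membership
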