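"""Gamma-Poisson background model for SNV/INDEL hotspot discovery.

Somatic point mutations pooled across donors are grouped into clusters by
single-linkage at a 200 bp gap; each cluster is the hypothesis unit. The
background model is a negative-binomial (Gamma-Poisson) regression of the
cluster mutation count on epigenomic covariates (chromatin accessibility,
replication timing, chromatin-state composition) plus local GC content,
with log cluster length as offset:

    y_i ~ NB(mu_i, theta),  log mu_i = log L_i + beta0 + beta' x_i,
    Var(y_i) = mu_i + mu_i^2 / theta.

beta is fit by iteratively reweighted least squares alternating with
Newton updates of the dispersion theta on the profile likelihood. Each
cluster's upper-tail probability P(Y >= y_i) under its fitted background is
corrected genome-wide by Benjamini-Hochberg; clusters at q < 0.05 are the
SNV/INDEL-associated highly recurrent regions.

An optional fixed-tile mode tests regular genome tiles instead of clusters,
with the same covariate machinery.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .intervals import Genome, GenomicInterval

logger = logging.getLogger(__name__)

THETA_CAP = 1e6


@dataclass(frozen=True)
class SnvCall:
    """One somatic point mutation (0-based position)."""

    donor_id: str
    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref must differ from alt")


@dataclass
class MutCluster:
    """A 200 bp-linkage mutation cluster: the hotspot-test hypothesis unit."""

    interval: GenomicInterval
    members: list[SnvCall]
    y: int  # distinct (donor, position, alt) events
    covariates: dict[str, float] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return len(self.interval)


@dataclass
class GpFit:
    """Fitted Gamma-Poisson background: coefficients and dispersion."""

    beta: np.ndarray
    theta: float
    loglik: float
    feature_names: list[str]
    converged: bool
    n_iter: int


@dataclass
class ClusterTest:
    cluster: MutCluster
    mu: float
    p: float
    q: float = float("nan")

    @property
    def significant(self) -> bool:
        return self.q < 0.05


class ConvergenceError(RuntimeError):
    def __init__(self, message: str, beta: np.ndarray, theta: float, grad_norm: float):
        super().__init__(message)
        self.beta = beta
        self.theta = theta
        self.grad_norm = grad_norm


def cluster_mutations(calls: list[SnvCall], gap: int = 200) -> list[MutCluster]:
    """Single-linkage clustering of pooled mutations at a positional gap.

    Consecutive mutated positions at most ``gap`` bp apart join one cluster
    (a 201 bp jump starts a new one). The cluster interval spans
    [min_pos, max_pos + 1); y counts each distinct (donor, position, alt)
    event once.
    """
    by_chrom: dict[str, list[SnvCall]] = {}
    for c in calls:
        by_chrom.setdefault(c.chrom, []).append(c)
    clusters: list[MutCluster] = []
    for chrom in sorted(by_chrom):
        chrom_calls = sorted(by_chrom[chrom], key=lambda c: c.pos)
        current: list[SnvCall] = []
        last_pos: int | None = None
        for c in chrom_calls:
            if last_pos is not None and c.pos - last_pos > gap:
                clusters.append(_finish_cluster(current))
                current = []
            current.append(c)
            last_pos = c.pos
        if current:
            clusters.append(_finish_cluster(current))
    return clusters


def _finish_cluster(members: list[SnvCall]) -> MutCluster:
    lo = min(c.pos for c in members)
    hi = max(c.pos for c in members)
    events = {(c.donor_id, c.pos, c.alt) for c in members}
    return MutCluster(
        GenomicInterval(members[0].chrom, lo, hi + 1), members, len(events)
    )


# ---------------------------------------------------------------------------
# covariates


@dataclass
class CovariateTracks:
    """Piecewise-constant covariate tracks over regular tiles.

    ``numeric`` maps a track name to {chrom: tile-value array}; ``state``
    holds a categorical chromatin-state label per tile. All tracks share one
    tile size. Gaps beyond the last tile are imputed as the track mean.
    """

    tile_size: int
    numeric: dict[str, dict[str, np.ndarray]]
    state: dict[str, np.ndarray] | None = None
    state_labels: tuple[str, ...] = ()

    def numeric_mean(self, name: str, iv: GenomicInterval) -> float:
        values = self.numeric[name].get(iv.chrom)
        if values is None:
            return float(np.mean([v.mean() for v in self.numeric[name].values()]))
        return _tile_weighted_mean(values, self.tile_size, iv.start, iv.end)

    def state_fractions(self, iv: GenomicInterval) -> dict[str, float]:
        assert self.state is not None
        labels = self.state.get(iv.chrom)
        fracs = dict.fromkeys(self.state_labels, 0.0)
        if labels is None:
            return fracs
        total = len(iv)
        for tile, lo, hi in _tile_spans(self.tile_size, iv.start, iv.end):
            if tile < len(labels):
                fracs[labels[tile]] += (hi - lo) / total
        return fracs


def _tile_spans(tile_size: int, start: int, end: int):
    t = start // tile_size
    while t * tile_size < end:
        lo = max(start, t * tile_size)
        hi = min(end, (t + 1) * tile_size)
        yield t, lo, hi
        t += 1


def _tile_weighted_mean(values: np.ndarray, tile_size: int, start: int, end: int) -> float:
    total = 0.0
    mean_fill = float(values.mean())
    for tile, lo, hi in _tile_spans(tile_size, start, end):
        v = values[tile] if tile < len(values) else mean_fill
        total += v * (hi - lo)
    return total / (end - start)


def attach_covariates(
    clusters: list[MutCluster],
    tracks: CovariateTracks,
    genome: Genome | None = None,
    gc: bool = True,
    include_log_length: bool = True,
    standardize: bool = True,
) -> list[str]:
    """Attach length-weighted covariates to each cluster, z-scored across clusters.

    Numeric tracks become length-weighted means over the cluster interval;
    the categorical state track becomes per-state bp fractions with the
    first (reference) state dropped; GC fraction is computed from sequence.
    ``include_log_length`` adds log cluster length as a free covariate on
    top of the offset, letting the fit correct for the empirical (sub-
    linear) count-length relation of linkage clusters. Zero-variance
    covariates are dropped with a warning. Returns the ordered feature
    names attached.
    """
    if gc and (genome is None or genome.sequences is None):
        raise ValueError("genome sequence required for the GC covariate")
    raw: dict[str, list[float]] = {name: [] for name in tracks.numeric}
    state_names = list(tracks.state_labels[1:]) if tracks.state is not None else []
    for s in state_names:
        raw[f"state_{s}"] = []
    if gc:
        raw["gc"] = []
    if include_log_length:
        raw["log_length"] = []
    for cl in clusters:
        for name in tracks.numeric:
            raw[name].append(tracks.numeric_mean(name, cl.interval))
        if tracks.state is not None:
            fracs = tracks.state_fractions(cl.interval)
            for s in state_names:
                raw[f"state_{s}"].append(fracs[s])
        if gc:
            seq = genome.fetch(cl.interval)
            raw["gc"].append(
                (seq.count("G") + seq.count("C")) / max(1, len(seq))
            )
        if include_log_length:
            raw["log_length"].append(float(np.log(cl.length)))
    kept: list[str] = []
    for name, vals in raw.items():
        arr = np.asarray(vals, dtype=float)
        sd = arr.std()
        if sd == 0:
            warnings.warn(f"covariate {name!r} is constant; dropped as degenerate")
            continue
        if standardize:
            arr = (arr - arr.mean()) / sd
        for cl, v in zip(clusters, arr):
            cl.covariates[name] = float(v)
        kept.append(name)
    return kept


# ---------------------------------------------------------------------------
# Gamma-Poisson fit


def _nb_loglik(y, mu, theta):
    return float(
        np.sum(
            special.gammaln(y + theta)
            - special.gammaln(theta)
            - special.gammaln(y + 1)
            + theta * np.log(theta / (theta + mu))
            + y * np.log(mu / (theta + mu))
        )
    )


def _irls_beta(y, X, offset, theta, beta, max_iter=50, tol=1e-10):
    """IRLS for NB2 regression coefficients at fixed dispersion."""
    for _ in range(max_iter):
        eta = offset + X @ beta
        mu = np.exp(np.clip(eta, -30, 30))
        w = mu / (1.0 + mu / theta)
        z = (eta - offset) + (y - mu) / mu
        WX = X * w[:, None]
        try:
            new = np.linalg.solve(X.T @ WX, WX.T @ z)
        except np.linalg.LinAlgError:
            new = np.linalg.lstsq(X.T @ WX, WX.T @ z, rcond=None)[0]
        if np.max(np.abs(new - beta)) < tol * (1 + np.max(np.abs(beta))):
            beta = new
            break
        beta = new
    return beta


def _theta_mle(y, mu, theta, max_iter=50):
    """Newton iterations for the NB dispersion on the profile likelihood."""
    lt = np.log(theta)
    for _ in range(max_iter):
        t = np.exp(lt)
        # d loglik / d theta
        g = np.sum(
            special.digamma(y + t)
            - special.digamma(t)
            + np.log(t / (t + mu))
            + 1.0
            - (y + t) / (t + mu)
        )
        h = np.sum(
            special.polygamma(1, y + t)
            - special.polygamma(1, t)
            + 1.0 / t
            - 2.0 / (t + mu)
            + (y + t) / (t + mu) ** 2
        )
        # Newton in log-space for positivity: d/dlt = g*t
        glt = g * t
        hlt = h * t * t + g * t
        if hlt >= 0:  # fall back to gradient step if not concave here
            step = 0.5 * np.sign(glt)
        else:
            step = -glt / hlt
        step = np.clip(step, -2.0, 2.0)
        lt = lt + step
        lt = min(lt, np.log(THETA_CAP))
        if abs(step) < 1e-10:
            break
    return float(np.exp(lt))


def fit_gamma_poisson(
    clusters: list[MutCluster],
    feature_names: list[str] | None = None,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> GpFit:
    """Fit the NB background y ~ NB(mu, theta), log mu = log L + beta'x.

    Alternates IRLS for beta with Newton maximum likelihood for theta until
    the relative log-likelihood change drops below ``tol``. Requires at
    least 10 clusters per coefficient. Near-Poisson data drives theta to the
    cap (1e6) with an under-dispersion warning rather than an error.
    """
    if feature_names is None:
        feature_names = sorted(clusters[0].covariates) if clusters else []
    n = len(clusters)
    p = len(feature_names) + 1
    if n < 10 * p:
        raise ValueError(f"need >= {10 * p} clusters to fit {p} coefficients, got {n}")
    y = np.array([c.y for c in clusters], dtype=float)
    L = np.array([c.length for c in clusters], dtype=float)
    offset = np.log(L)
    X = np.column_stack(
        [np.ones(n)] + [np.array([c.covariates[f] for c in clusters]) for f in feature_names]
    )
    beta = np.zeros(p)
    beta[0] = np.log(max(y.mean(), 0.1)) - np.log(L.mean())
    theta = 10.0
    prev_ll = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        beta = _irls_beta(y, X, offset, theta, beta)
        mu = np.exp(np.clip(offset + X @ beta, -30, 30))
        theta = _theta_mle(y, mu, theta)
        ll = _nb_loglik(y, mu, theta)
        if np.isfinite(prev_ll) and abs(ll - prev_ll) < tol * (1 + abs(prev_ll)):
            converged = True
            prev_ll = ll
            break
        prev_ll = ll
    mu = np.exp(np.clip(offset + X @ beta, -30, 30))
    if not converged:
        w = mu / (1.0 + mu / theta)
        grad = X.T @ ((y - mu) / mu * w)
        raise ConvergenceError(
            f"Gamma-Poisson fit did not converge in {max_iter} iterations "
            f"(|grad| = {np.linalg.norm(grad):.3g})",
            beta,
            theta,
            float(np.linalg.norm(grad)),
        )
    if theta >= THETA_CAP * 0.999:
        warnings.warn(
            "dispersion at cap: data show no over-dispersion (Poisson-like)"
        )
    if not np.all(np.isfinite(beta)):
        raise ConvergenceError("non-finite coefficients", beta, theta, np.nan)
    return GpFit(beta, theta, prev_ll, list(feature_names), converged, it)


def nb_tail(y: float, mu: float, theta: float) -> float:
    """Exact upper tail P(Y >= y) under NB(mu, theta); P(Y >= 0) = 1."""
    if y <= 0:
        return 1.0
    # scipy parameterization: nbinom(n=theta, p=theta/(theta+mu))
    return float(stats.nbinom.sf(y - 1, theta, theta / (theta + mu)))


def test_clusters(
    clusters: list[MutCluster], fit: GpFit, fdr: float = 0.05
) -> list[ClusterTest]:
    """Upper-tail NB test per cluster with genome-wide BH correction."""
    y = np.array([c.y for c in clusters], dtype=float)
    X = np.column_stack(
        [np.ones(len(clusters))]
        + [np.array([c.covariates[f] for c in clusters]) for f in fit.feature_names]
    )
    offset = np.log(np.array([c.length for c in clusters], dtype=float))
    mu = np.exp(np.clip(offset + X @ fit.beta, -30, 30))
    pvals = np.array([nb_tail(yi, mi, fit.theta) for yi, mi in zip(y, mu)])
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    return [
        ClusterTest(c, float(m), float(p), float(q))
        for c, m, p, q in zip(clusters, mu, pvals, qvals)
    ]


def fit_and_test(
    clusters: list[MutCluster],
    feature_names: list[str] | None = None,
    fdr: float = 0.05,
    robust: bool = True,
) -> tuple[GpFit, list[ClusterTest]]:
    """Fit the background and test every cluster, with a robust refit.

    With ``robust`` (default), the background is fit twice: clusters called
    significant by the first pass are excluded from the second fit, so true
    hotspots do not inflate the dispersion estimate and mask themselves.
    All clusters are tested against the final background either way.
    """
    fit = fit_gamma_poisson(clusters, feature_names)
    tests = test_clusters(clusters, fit, fdr)
    if robust:
        flagged = {id(t.cluster) for t in tests if t.q < fdr}
        if flagged:
            background = [c for c in clusters if id(c) not in flagged]
            p = len(fit.feature_names) + 1
            if len(background) >= 10 * p:
                fit = fit_gamma_poisson(background, fit.feature_names)
                tests = test_clusters(clusters, fit, fdr)
    return fit, tests


def significant_intervals(tests: list[ClusterTest], fdr: float = 0.05) -> list[GenomicInterval]:
    return [t.cluster.interval for t in tests if t.q < fdr]


# ---------------------------------------------------------------------------
# fixed-tile mode


def tile_mutations(
    calls: list[SnvCall], genome: Genome, tile_size: int = 1000
) -> list[MutCluster]:
    """Alternative hypothesis units: regular genome tiles holding >= 1 event."""
    buckets: dict[tuple[str, int], list[SnvCall]] = {}
    for c in calls:
        buckets.setdefault((c.chrom, c.pos // tile_size), []).append(c)
    out = []
    for (chrom, t), members in sorted(buckets.items()):
        start = t * tile_size
        end = min(start + tile_size, genome.lengths[chrom])
        events = {(c.donor_id, c.pos, c.alt) for c in members}
        out.append(
            MutCluster(GenomicInterval(chrom, start, end), members, len(events))
        )
    return out
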