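"""SBS-96 mutational-signature analysis.

Single-base substitutions are classified into the conventional 96 categories
(6 pyrimidine-strand substitution classes x 16 flanking-base contexts).
De novo signatures are extracted by non-negative matrix factorization under
the generalized Kullback-Leibler divergence — the count-appropriate
objective — with multiplicative updates and multiple restarts, and matched
to a reference catalog by cosine similarity. The bundled catalog holds two
synthetic stand-in profiles (a UV-like C>T profile and a platinum-like
profile) for testing; matching against the real COSMIC catalog requires the
user to supply its file.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import Genome, GenomicInterval

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: Fixed category order: substitution class major, flanks alphabetical.
SBS96_CATEGORIES: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in "ACGT"
    for three in "ACGT"
)

_CATEGORY_INDEX = {c: i for i, c in enumerate(SBS96_CATEGORIES)}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def classify_sbs(context: str, ref: str, alt: str) -> str | None:
    """Map a substitution with trinucleotide context to its SBS-96 category.

    Purine-reference events are reverse-complemented to the pyrimidine
    strand. Returns None when the context contains a non-ACGT base.
    """
    if len(context) != 3 or any(b not in "ACGT" for b in context):
        return None
    if ref not in "ACGT" or alt not in "ACGT" or ref == alt:
        return None
    if context[1] != ref:
        raise ValueError(f"context {context} center does not match ref {ref}")
    if ref in "AG":
        context = revcomp(context)
        ref = ref.translate(_COMPLEMENT)
        alt = alt.translate(_COMPLEMENT)
    return f"{context[0]}[{ref}>{alt}]{context[2]}"


@dataclass
class Signature:
    """A normalized 96-category mutational-process profile."""

    weights: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (96,):
            raise ValueError("signature must have 96 entries")
        if (w < 0).any():
            raise ValueError("signature entries must be non-negative")
        total = w.sum()
        if total <= 0:
            raise ValueError("signature must have positive mass")
        self.weights = w / total


def build_sbs_matrix(
    snvs,
    genome: Genome,
    regions: list[GenomicInterval] | None = None,
    sample_of=None,
) -> tuple[pd.DataFrame, int]:
    """Count SBS-96 categories per sample from substitution calls.

    ``snvs`` is an iterable of objects with ``donor_id, chrom, pos, ref,
    alt`` (0-based positions). Non-single-base events are skipped and
    counted. ``regions``, when given, restricts to calls overlapping any
    region (the enhancer-restricted use). ``sample_of`` maps a donor id to a
    sample label (default: one column per donor). Returns (matrix with 96
    category rows x sample columns, number of skipped events).
    """
    if genome.sequences is None:
        raise ValueError("genome sequence required for trinucleotide contexts")
    by_chrom: dict[str, list[GenomicInterval]] = {}
    if regions is not None:
        for r in regions:
            by_chrom.setdefault(r.chrom, []).append(r)
    counts: dict[str, np.ndarray] = {}
    skipped = 0
    for call in snvs:
        if len(call.ref) != 1 or len(call.alt) != 1:
            skipped += 1
            continue
        if regions is not None:
            hits = by_chrom.get(call.chrom, ())
            if not any(r.start <= call.pos < r.end for r in hits):
                continue
        seq = genome.sequences[call.chrom]
        if call.pos < 1 or call.pos >= len(seq) - 1:
            skipped += 1
            continue
        context = seq[call.pos - 1 : call.pos + 2]
        try:
            cat = classify_sbs(context, call.ref, call.alt)
        except ValueError:
            skipped += 1
            continue
        if cat is None:
            skipped += 1
            logger.debug("skipping event with ambiguous context %s", context)
            continue
        sample = sample_of(call.donor_id) if sample_of else call.donor_id
        col = counts.setdefault(sample, np.zeros(96, dtype=int))
        col[_CATEGORY_INDEX[cat]] += 1
    matrix = pd.DataFrame(
        counts, index=list(SBS96_CATEGORIES), dtype=int
    ).reindex(columns=sorted(counts))
    if matrix.empty:
        matrix = pd.DataFrame(index=list(SBS96_CATEGORIES), dtype=int)
    return matrix, skipped


def _kl_divergence(V: np.ndarray, WH: np.ndarray) -> float:
    mask = V > 0
    eps = 1e-12
    return float(
        (V[mask] * np.log(V[mask] / (WH[mask] + eps))).sum() - V.sum() + WH.sum()
    )


def _kl_nmf_once(
    V: np.ndarray,
    k: int,
    rng: np.random.Generator,
    max_iter: int,
    tol: float,
    check_monotone: bool,
) -> tuple[np.ndarray, np.ndarray, float]:
    n, m = V.shape
    eps = 1e-12
    W = rng.uniform(0.5, 1.5, size=(n, k)) * (V.mean() or 1.0)
    H = rng.uniform(0.5, 1.5, size=(k, m))
    prev = _kl_divergence(V, W @ H)
    for _ in range(max_iter):
        WH = W @ H + eps
        H *= (W.T @ (V / WH)) / (W.sum(axis=0)[:, None] + eps)
        WH = W @ H + eps
        W *= ((V / WH) @ H.T) / (H.sum(axis=1)[None, :] + eps)
        obj = _kl_divergence(V, W @ H)
        if check_monotone and obj > prev + 1e-6 * max(1.0, abs(prev)):
            raise AssertionError(
                f"KL objective increased: {prev:.6g} -> {obj:.6g}"
            )
        if abs(prev - obj) < tol * max(1.0, abs(prev)):
            prev = obj
            break
        prev = obj
    return W, H, prev


def extract_signatures(
    matrix: pd.DataFrame,
    k: int,
    seed: int,
    n_restarts: int = 20,
    max_iter: int = 2000,
    tol: float = 1e-9,
    objective: str = "kl",
) -> tuple[list[Signature], pd.DataFrame]:
    """De novo signature extraction by KL-NMF with multiplicative updates.

    Runs ``n_restarts`` seeded restarts and keeps the factorization with the
    lowest objective. Signatures are column-normalized to sum to one, with
    exposures rescaled accordingly. ``objective`` may be ``"kl"`` (default,
    count-appropriate) or ``"frobenius"``.

    Returns (signatures, exposures DataFrame of shape k x samples).
    """
    V = matrix.to_numpy(dtype=float)
    if V.size == 0 or V.sum() <= 0:
        raise ValueError("cannot factorize an all-zero matrix")
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    best: tuple[np.ndarray, np.ndarray, float] | None = None
    for r in range(n_restarts):
        sub = np.random.default_rng(rng.integers(0, 2**31 - 1))
        if objective == "kl":
            W, H, obj = _kl_nmf_once(V, k, sub, max_iter, tol, check_monotone=True)
        elif objective == "frobenius":
            W, H, obj = _frobenius_nmf_once(V, k, sub, max_iter, tol)
        else:
            raise ValueError(f"unknown objective {objective!r}")
        if best is None or obj < best[2]:
            best = (W, H, obj)
    W, H, _ = best
    scale = W.sum(axis=0)
    scale[scale == 0] = 1.0
    W = W / scale
    H = H * scale[:, None]
    # order components by total exposure, largest first, for stable output
    order = np.argsort(-H.sum(axis=1))
    W, H = W[:, order], H[order]
    sigs = [Signature(W[:, i], label=f"denovo_{i + 1}") for i in range(k)]
    exposures = pd.DataFrame(
        H, index=[s.label for s in sigs], columns=matrix.columns
    )
    return sigs, exposures


def _frobenius_nmf_once(V, k, rng, max_iter, tol):
    eps = 1e-12
    n, m = V.shape
    W = rng.uniform(0.5, 1.5, size=(n, k)) * (np.sqrt(V.mean() / k) or 1.0)
    H = rng.uniform(0.5, 1.5, size=(k, m))
    prev = float(((V - W @ H) ** 2).sum())
    for _ in range(max_iter):
        H *= (W.T @ V) / (W.T @ W @ H + eps)
        W *= (V @ H.T) / (W @ H @ H.T + eps)
        obj = float(((V - W @ H) ** 2).sum())
        if abs(prev - obj) < tol * max(1.0, abs(prev)):
            prev = obj
            break
        prev = obj
    return W, H, prev


def elbow_report(
    matrix: pd.DataFrame, k_max: int = 5, seed: int = 0, n_restarts: int = 5,
    max_iter: int = 500,
) -> pd.DataFrame:
    """Objective value for k = 1..k_max, to guide the (user-made) choice of k."""
    rows = []
    V = matrix.to_numpy(dtype=float)
    for k in range(1, k_max + 1):
        rng = np.random.default_rng(seed + k)
        best = np.inf
        for _ in range(n_restarts):
            sub = np.random.default_rng(rng.integers(0, 2**31 - 1))
            _, _, obj = _kl_nmf_once(V, k, sub, max_iter, 1e-7, True)
            best = min(best, obj)
        rows.append({"k": k, "kl_objective": best})
    return pd.DataFrame(rows)


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine undefined for a zero vector")
    return float(u @ v / (nu * nv))


def match_cosmic(
    sig: Signature, catalog: list[Signature]
) -> list[tuple[str, float]]:
    """Rank catalog signatures by cosine similarity; the top entry is the call."""
    if not catalog:
        raise ValueError("catalog is empty")
    scored = [(c.label, cosine_similarity(sig.weights, c.weights)) for c in catalog]
    return sorted(scored, key=lambda t: -t[1])


def read_catalog(path: str) -> list[Signature]:
    """Read a catalog TSV: first column the 96 contexts, one column per label."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df = df.reindex(list(SBS96_CATEGORIES))
    if df.isna().any().any():
        raise ValueError("catalog does not cover the 96 categories")
    return [Signature(df[col].to_numpy(), label=col) for col in df.columns]


def load_builtin_catalog() -> list[Signature]:
    """The bundled synthetic stand-in catalog (UV-like and platinum-like)."""
    ref = importlib.resources.files("hrrscan.data") / "synthetic_sbs_catalog.tsv"
    with importlib.resources.as_file(ref) as path:
        return read_catalog(str(path))


def uv_like_profile() -> Signature:
    """Synthetic UV-like profile: C>T concentrated at dipyrimidine contexts.

    A stand-in for the ultraviolet signature's shape (dominant C>T at
    TpC/CpC), not the COSMIC SBS7a vector itself.
    """
    w = np.zeros(96)
    for i, cat in enumerate(SBS96_CATEGORIES):
        five, sub, three = cat[0], cat[2:5], cat[6]
        if sub == "C>T":
            if five in "CT":  # 5' pyrimidine: dipyrimidine site
                w[i] = 10.0
            else:
                w[i] = 1.0
        elif sub == "C>A":
            w[i] = 0.1
    return Signature(w, label="UV_like")


def platinum_like_profile() -> Signature:
    """Synthetic platinum-like profile: mixed C>T/T>A with 5'-purine bias.

    A stand-in with the broad shape of a platinum-treatment signature
    (C>T at 5'-purine contexts plus T>A), not the COSMIC SBS31 vector.
    """
    w = np.zeros(96)
    for i, cat in enumerate(SBS96_CATEGORIES):
        five, sub, three = cat[0], cat[2:5], cat[6]
        if sub == "C>T" and five in "AG":
            w[i] = 6.0
        elif sub == "T>A":
            w[i] = 3.0
        elif sub == "C>G":
            w[i] = 0.5
    return Signature(w, label="Platinum_like")
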