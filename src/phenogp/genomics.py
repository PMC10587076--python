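"""Genotype coding, SNP filtering, diversity statistics and genomic
relationship matrices for hybrid panels.

Genotypes of N hybrids at L biallelic SNPs are held as an N x L integer
matrix coded 0 (homozygote for the reference allele, the "B73 role"),
1 (heterozygote), 2 (the other homozygote); -1 marks a missing call.

Two relationship matrices are built from the coded matrix:

* the additive (realized) relationship matrix
  ``G_A = H_a H_a' / (tr(H_a H_a')/N)`` with ``H_a = M - 2 p_j``;
* the dominance relationship matrix
  ``G_D = H_d H_d' / (tr(H_d H_d')/N)`` where the per-locus dominance
  score depends on the genotypic frequencies (p_BB, p_Bb, p_bb):

  ======== =====================================================
  genotype h_d
  ======== =====================================================
  BB       -2 p_Bb p_bb / [p_BB + p_bb - (p_BB - p_bb)^2]
  Bb        4 p_BB p_bb / [p_BB + p_bb - (p_BB - p_bb)^2]
  bb       -2 p_Bb p_BB / [p_BB + p_bb - (p_BB - p_bb)^2]
  ======== =====================================================

Both matrices are scaled so that their trace equals N.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

MISSING = -1


class EmptyPanelError(ValueError):
    """All loci (or hybrids) were removed by a filter."""


class MonomorphicPanelError(ValueError):
    """No polymorphic locus left to build a relationship matrix from."""


@dataclass
class GenotypeMatrix:
    """N hybrids x L loci in {0,1,2} coding, -1 for missing.

    ``codes`` rows follow ``hybrid_ids``; columns follow ``locus_ids``.
    ``groups`` carries one genetic-group label per hybrid (may be None).
    """

    codes: np.ndarray
    hybrid_ids: list[str] = field(default_factory=list)
    locus_ids: list[str] = field(default_factory=list)
    groups: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        if self.codes.ndim != 2:
            raise ValueError("codes must be a 2-D matrix (hybrids x loci)")
        bad = ~np.isin(self.codes, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid genotype code {self.codes[i, j]} at hybrid {i}, locus {j}; "
                "expected 0/1/2 or -1 for missing"
            )
        if not self.hybrid_ids:
            self.hybrid_ids = [f"H{i:04d}" for i in range(self.codes.shape[0])]
        if not self.locus_ids:
            self.locus_ids = [f"snp{j:05d}" for j in range(self.codes.shape[1])]
        if len(self.hybrid_ids) != self.codes.shape[0]:
            raise ValueError("hybrid_ids length does not match codes rows")
        if len(self.locus_ids) != self.codes.shape[1]:
            raise ValueError("locus_ids length does not match codes columns")
        if self.groups is not None:
            self.groups = np.asarray(self.groups)
            if self.groups.shape[0] != self.codes.shape[0]:
                raise ValueError("groups length does not match codes rows")

    @property
    def n_hybrids(self) -> int:
        return self.codes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.codes.shape[1]

    @property
    def missing_fraction(self) -> np.ndarray:
        """Per-locus fraction of missing calls."""
        return (self.codes == MISSING).mean(axis=0)

    def allele_freq(self) -> np.ndarray:
        """Reference-allele frequency p_j per locus, over non-missing calls.

        Code 0 is the reference homozygote, so p_j = 1 - mean(code)/2.
        """
        codes = np.ma.masked_equal(self.codes, MISSING)
        n_obs = codes.count(axis=0)
        if (n_obs == 0).any():
            raise ValueError("locus with no observed calls; filter first")
        return np.asarray(1.0 - codes.mean(axis=0) / 2.0)

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def genotypic_freqs(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(p_BB, p_Bb, p_bb) per locus over non-missing calls."""
        obs = self.codes != MISSING
        n_obs = obs.sum(axis=0)
        p_bb_ = (self.codes == 2).sum(axis=0) / n_obs
        p_het = (self.codes == 1).sum(axis=0) / n_obs
        p_BB = (self.codes == 0).sum(axis=0) / n_obs
        return p_BB, p_het, p_bb_


@dataclass
class RelationshipPair:
    """Additive and dominance relationship matrices with their scalings."""

    g_add: np.ndarray
    g_dom: np.ndarray | None
    denom_add: float
    denom_dom: float | None
    hybrid_ids: list[str]


def filter_snps(
    g: GenotypeMatrix, maf_min: float = 0.05, max_missing_fraction: float = 0.20
) -> GenotypeMatrix:
    """Drop loci with MAF < ``maf_min`` or missing fraction > ``max_missing_fraction``.

    Locus order is preserved; the removed count is logged.
    """
    if not 0.0 <= maf_min <= 0.5:
        raise ValueError("maf_min must be in [0, 0.5]")
    if not 0.0 <= max_missing_fraction <= 1.0:
        raise ValueError("max_missing_fraction must be in [0, 1]")
    miss_ok = g.missing_fraction <= max_missing_fraction
    # compute MAF only where some calls exist
    codes = np.ma.masked_equal(g.codes, MISSING)
    n_obs = codes.count(axis=0)
    p = np.where(n_obs > 0, 1.0 - np.asarray(codes.mean(axis=0)) / 2.0, np.nan)
    maf = np.minimum(p, 1.0 - p)
    keep = miss_ok & (maf >= maf_min)
    n_removed = int((~keep).sum())
    logger.info("filter_snps: removed %d of %d loci", n_removed, g.n_loci)
    if not keep.any():
        raise EmptyPanelError("all loci removed by MAF/missingness filter")
    return replace(
        g,
        codes=g.codes[:, keep],
        locus_ids=[lid for lid, k in zip(g.locus_ids, keep) if k],
    )


def impute_missing(g: GenotypeMatrix, method: str = "mean") -> GenotypeMatrix:
    """Fill missing codes.

    method "mean": fill with the locus mean code 2(1-p_j) (continuous values,
    preserves p_j exactly); method "mean_rounded" rounds to the nearest code;
    method "mode": most frequent observed code.
    """
    if method not in ("mean", "mean_rounded", "mode"):
        raise ValueError(f"unknown imputation method {method!r}; use mean/mean_rounded/mode")
    if not (g.codes == MISSING).any():
        return g
    codes = g.codes.astype(float)
    missing = g.codes == MISSING
    if method in ("mean", "mean_rounded"):
        masked = np.ma.masked_equal(g.codes, MISSING)
        fill = np.asarray(masked.mean(axis=0))
        if method == "mean_rounded":
            fill = np.rint(fill)
        codes[missing] = np.broadcast_to(fill, codes.shape)[missing]
    else:
        for j in np.where(missing.any(axis=0))[0]:
            col = g.codes[:, j]
            obs = col[col != MISSING]
            vals, counts = np.unique(obs, return_counts=True)
            codes[missing[:, j], j] = vals[np.argmax(counts)]
    if method == "mean":
        out = replace(g, codes=g.codes)  # shallow copy of metadata
        out.codes = codes  # float matrix; bypass 0/1/2 validation
        return out
    return replace(g, codes=codes.astype(g.codes.dtype))


def _require_complete(g: GenotypeMatrix) -> np.ndarray:
    codes = np.asarray(g.codes, dtype=float)
    if np.isin(codes, MISSING).any():
        raise ValueError("matrix contains missing codes; impute first")
    return codes


def observed_heterozygosity(g: GenotypeMatrix) -> float:
    """Mean per-locus heterozygote fraction: (1/L) sum_j nH_j / N."""
    codes = _require_complete(g)
    if g.n_loci == 0:
        raise EmptyPanelError("no loci")
    return float((codes == 1).mean())


def nei_diversity(g: GenotypeMatrix) -> float:
    """Nei's expected heterozygosity: (1/L) sum_j (1 - p_j^2 - (1-p_j)^2)."""
    _require_complete(g)
    if g.n_loci == 0:
        raise EmptyPanelError("no loci")
    p = g.allele_freq()
    return float(np.mean(1.0 - p**2 - (1.0 - p) ** 2))


def additive_coding(g: GenotypeMatrix) -> np.ndarray:
    """Centered additive scores H_a = M - 2(1-p_j) (column means removed)."""
    codes = _require_complete(g)
    return codes - codes.mean(axis=0)


def dominance_coding(
    g: GenotypeMatrix, on_zero_denominator: str = "drop"
) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus dominance scores h_d from genotypic frequencies.

    Returns (H_d, kept) where ``kept`` flags loci whose denominator
    p_BB + p_bb - (p_BB - p_bb)^2 is positive. Zero-denominator loci are
    dropped with a log message (default) or raise, per ``on_zero_denominator``.
    Non-integer (mean-imputed) codes are assigned the nearest genotype class.
    """
    codes = _require_complete(g)
    p_BB, p_Bb, p_bb = GenotypeMatrix(
        np.rint(codes).astype(int), list(g.hybrid_ids), list(g.locus_ids)
    ).genotypic_freqs()
    denom = p_BB + p_bb - (p_BB - p_bb) ** 2
    kept = denom > 1e-12
    if not kept.all():
        msg = f"dominance coding: {int((~kept).sum())} loci with zero denominator"
        if on_zero_denominator == "drop":
            logger.warning("%s; dropped", msg)
        elif on_zero_denominator == "raise":
            raise ZeroDivisionError(msg)
        else:
            raise ValueError("on_zero_denominator must be 'drop' or 'raise'")
    d = np.where(kept, denom, 1.0)
    h_BB = -2.0 * p_Bb * p_bb / d
    h_Bb = 4.0 * p_BB * p_bb / d
    h_bb = -2.0 * p_Bb * p_BB / d
    rounded = np.rint(codes).astype(int)
    h = np.choose(rounded, (h_BB, h_Bb, h_bb))
    return h[:, kept], kept


def _scale_grm(h: np.ndarray, n: int) -> tuple[np.ndarray, float]:
    cross = h @ h.T
    denom = float(np.trace(cross)) / n
    if denom <= 0.0:
        raise MonomorphicPanelError(
            "zero relationship-matrix denominator (no polymorphic information)"
        )
    return cross / denom, denom


def additive_grm(g: GenotypeMatrix) -> tuple[np.ndarray, float]:
    """G_A = H_a H_a'/(tr(H_a H_a')/N); trace(G_A) = N."""
    return _scale_grm(additive_coding(g), g.n_hybrids)


def dominance_grm(
    g: GenotypeMatrix, on_zero_denominator: str = "drop"
) -> tuple[np.ndarray, float]:
    """G_D = H_d H_d'/(tr(H_d H_d')/N); trace(G_D) = N."""
    h, _ = dominance_coding(g, on_zero_denominator)
    if h.shape[1] == 0:
        raise MonomorphicPanelError("no locus carries dominance information")
    return _scale_grm(h, g.n_hybrids)


def relationship_matrices(g: GenotypeMatrix, dominance: bool = True) -> RelationshipPair:
    """Build the additive (and optionally dominance) relationship matrices."""
    g_add, denom_a = additive_grm(g)
    g_dom = denom_d = None
    if dominance:
        g_dom, denom_d = dominance_grm(g)
    return RelationshipPair(g_add, g_dom, denom_a, denom_d, list(g.hybrid_ids))


def pcoa(
    g: GenotypeMatrix, n_axes: int = 5, distance: str = "euclidean"
) -> tuple[np.ndarray, np.ndarray]:
    """Classical metric scaling (PCoA) of a hybrid distance matrix.

    distance "euclidean": Euclidean distance between centered code rows
    (equivalent to PCA of the coded matrix); "ibs": 1 - proportion of
    shared alleles. Returns (coordinates N x n_axes, explained-variance
    fractions), axes ordered by decreasing eigenvalue.
    """
    if g.n_hybrids < 3:
        raise ValueError("PCoA needs at least 3 hybrids")
    if n_axes > g.n_hybrids - 1:
        raise ValueError(f"n_axes={n_axes} exceeds N-1={g.n_hybrids - 1}")
    codes = _require_complete(g)
    if distance == "euclidean":
        x = codes - codes.mean(axis=0)
        sq = ((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2) if g.n_loci < 64 else None
        if sq is None:
            norms = (x**2).sum(axis=1)
            sq = np.maximum(norms[:, None] + norms[None, :] - 2.0 * x @ x.T, 0.0)
    elif distance == "ibs":
        # shared-allele proportion: 1 - mean(|c_i - c_j|)/2 over loci
        diff = np.abs(codes[:, None, :] - codes[None, :, :]).mean(axis=2) / 2.0
        sq = diff**2
    else:
        raise ValueError(f"unknown distance {distance!r}; use 'euclidean' or 'ibs'")
    n = sq.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ sq @ j
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = eigval > 1e-10 * max(eigval.max(), 1.0)
    total = eigval[pos].sum()
    coords = eigvec[:, :n_axes] * np.sqrt(np.maximum(eigval[:n_axes], 0.0))
    explained = np.maximum(eigval[:n_axes], 0.0) / total
    return coords, explained
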