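"""Distance-based ordination: classical PCoA and permutation PERMANOVA.

PCoA embeds the samples from their Euclidean distance matrix by
eigendecomposition of the Gower-centred matrix -1/2 J D^2 J. PERMANOVA
partitions the squared inter-sample distances into between- and
within-group components (Anderson's pseudo-F) and obtains a p-value by
permuting group labels; with the study's small sample counts the label
permutations are enumerated exactly whenever feasible.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core_io import FactorGrouping, FeatureMatrix

logger = logging.getLogger(__name__)

DEFAULT_N_PERM = 999
EXACT_ENUMERATION_LIMIT = 10_000


def euclidean_distances(fm: FeatureMatrix) -> np.ndarray:
    """Pairwise Euclidean distance matrix between samples."""
    if fm.missing_mask.any():
        raise ValueError(
            "distance matrix requires a complete matrix; impute missing "
            "cells first (see vinomics.preprocess)"
        )
    X = fm.values
    sq = np.sum(X**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2 * X @ X.T
    np.fill_diagonal(d2, 0.0)
    return np.sqrt(np.maximum(d2, 0.0))


@dataclass
class OrdinationResult:
    """PCoA coordinates with eigenvalues and variable loadings."""

    sample_ids: list[str]
    coordinates: np.ndarray  # samples x axes (positive-eigenvalue axes)
    eigenvalues: np.ndarray  # all eigenvalues, non-increasing
    explained: np.ndarray  # per retained axis, fraction of positive sum
    loadings: np.ndarray | None = field(default=None, repr=False)
    loading_ids: list[str] | None = None

    def to_dict(self) -> dict:
        return {
            "sample_ids": self.sample_ids,
            "coordinates": self.coordinates.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "explained": self.explained.tolist(),
            "loadings": None if self.loadings is None else self.loadings.tolist(),
            "loading_ids": self.loading_ids,
        }


def pcoa(dm: np.ndarray, sample_ids: list[str] | None = None) -> OrdinationResult:
    """Classical principal coordinate analysis of a distance matrix.

    Coordinates are eigenvectors of the double-centred -1/2 D^2 matrix
    scaled by sqrt(eigenvalue); axes with non-positive eigenvalues are not
    embedded. Each axis's sign is fixed so its largest-magnitude coordinate
    is positive. ``explained`` is eigenvalue over the sum of positive
    eigenvalues.
    """
    dm = np.asarray(dm, dtype=float)
    n = dm.shape[0]
    if dm.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if n < 3:
        raise ValueError("pcoa requires at least 3 samples")
    if not np.allclose(dm, dm.T):
        raise ValueError("distance matrix must be symmetric")
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n)]

    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (dm**2) @ J
    eigval, eigvec = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]

    tol = max(abs(eigval[0]), 1.0) * 1e-12
    pos = eigval > tol
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    # deterministic sign: largest-|coordinate| entry positive on each axis
    for k in range(coords.shape[1]):
        i = np.argmax(np.abs(coords[:, k]))
        if coords[i, k] < 0:
            coords[:, k] = -coords[:, k]
    pos_sum = eigval[pos].sum()
    explained = eigval[pos] / pos_sum if pos_sum > 0 else eigval[pos]
    return OrdinationResult(
        sample_ids=list(sample_ids),
        coordinates=coords,
        eigenvalues=eigval,
        explained=explained,
    )


def loadings(fm: FeatureMatrix, ordn: OrdinationResult) -> np.ndarray:
    """Pearson correlation of each metabolite with each coordinate axis.

    The standard biplot reading of 'loadings' for a PCoA: a metabolite
    loads on an axis in proportion to how its values track the sample
    scores. Zero-variance metabolites get loading 0 and are logged.
    """
    if fm.sample_ids != ordn.sample_ids:
        raise ValueError("feature matrix and ordination sample ids differ")
    if fm.missing_mask.any():
        raise ValueError("loadings require a complete matrix")
    X = fm.values
    C = ordn.coordinates
    out = np.zeros((fm.n_metabolites, C.shape[1]))
    Xc = X - X.mean(axis=0)
    Cc = C - C.mean(axis=0)
    xsd = Xc.std(axis=0)
    csd = Cc.std(axis=0)
    flagged = np.where(xsd == 0)[0]
    for j in flagged:
        logger.info("zero-variance metabolite %s: loading set to 0",
                    fm.metabolite_ids[j])
    ok = xsd > 0
    out[ok] = (Xc[:, ok].T @ Cc) / (fm.n_samples * np.outer(xsd[ok], csd))
    ordn.loadings = out
    ordn.loading_ids = list(fm.metabolite_ids)
    return out


@dataclass
class PermanovaResult:
    pseudo_F: float
    p_value: float
    n_permutations: int
    seed: int | None
    exact: bool
    ss_between: float
    ss_within: float

    def to_dict(self) -> dict:
        return {
            "pseudo_F": self.pseudo_F,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "exact": self.exact,
            "ss_between": self.ss_between,
            "ss_within": self.ss_within,
        }


def _pseudo_f(d2: np.ndarray, labels: np.ndarray, a: int) -> tuple[float, float, float]:
    """Anderson's pseudo-F from a squared distance matrix and labels."""
    n = d2.shape[0]
    ss_total = d2.sum() / (2 * n)
    ss_within = 0.0
    for g in range(a):
        idx = labels == g
        ng = idx.sum()
        ss_within += d2[np.ix_(idx, idx)].sum() / (2 * ng)
    ss_between = ss_total - ss_within
    if ss_within == 0:
        return math.inf, ss_between, ss_within
    f = (ss_between / (a - 1)) / (ss_within / (n - a))
    return f, ss_between, ss_within


def _n_distinct_assignments(sizes: list[int]) -> int:
    """Distinct label assignments up to relabeling equal-size groups."""
    n = sum(sizes)
    total = math.factorial(n)
    for s in sizes:
        total //= math.factorial(s)
    sym = 1
    for count in np.unique(sizes, return_counts=True)[1]:
        sym *= math.factorial(int(count))
    return total // sym


def permanova(
    dm: np.ndarray,
    grouping: FactorGrouping,
    sample_ids: list[str],
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> PermanovaResult:
    """Permutation test of group separation on a distance matrix.

    The observed pseudo-F is compared against label permutations. When the
    number of distinct assignments is at most 10,000 every assignment is
    enumerated and the p-value is the exact fraction with F >= F_obs
    (observed included); otherwise ``n_perm`` random permutations give
    p = (1 + #{F_perm >= F_obs}) / (1 + n_perm).
    """
    dm = np.asarray(dm, dtype=float)
    pos = {s: i for i, s in enumerate(sample_ids)}
    idx, labels = [], []
    for g, (label, ids) in enumerate(grouping.groups.items()):
        if len(ids) < 2:
            raise ValueError(f"group {label!r} has fewer than 2 samples")
        for s in ids:
            idx.append(pos[s])
            labels.append(g)
    idx = np.asarray(idx)
    labels = np.asarray(labels)
    d2 = dm[np.ix_(idx, idx)] ** 2
    a = len(grouping.groups)
    n = len(labels)
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")

    f_obs, ss_b, ss_w = _pseudo_f(d2, labels, a)
    eps = 1e-12 * max(abs(f_obs), 1.0) if math.isfinite(f_obs) else 0.0

    sizes = [int((labels == g).sum()) for g in range(a)]
    n_distinct = _n_distinct_assignments(sizes)
    if n_distinct <= EXACT_ENUMERATION_LIMIT:
        count = total = 0
        for lab in _enumerate_assignments(sizes):
            f, _, _ = _pseudo_f(d2, lab, a)
            total += 1
            if f >= f_obs - eps:
                count += 1
        p = count / total
        return PermanovaResult(
            pseudo_F=f_obs, p_value=p, n_permutations=total, seed=None,
            exact=True, ss_between=ss_b, ss_within=ss_w,
        )

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        f, _, _ = _pseudo_f(d2, perm, a)
        if f >= f_obs - eps:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return PermanovaResult(
        pseudo_F=f_obs, p_value=p, n_permutations=n_perm, seed=seed,
        exact=False, ss_between=ss_b, ss_within=ss_w,
    )


def _enumerate_assignments(sizes: list[int]):
    """Yield every multiset permutation of the group-label vector."""
    n = sum(sizes)
    if len(sizes) == 2:
        base = np.ones(n, dtype=int)
        for combo in itertools.combinations(range(n), sizes[0]):
            lab = base.copy()
            lab[list(combo)] = 0
            yield lab
        return

    def rec(remaining: list[int], slots: list[int]):
        if len(remaining) == 1:
            lab = np.empty(n, dtype=int)
            lab[slots] = len(sizes) - 1
            yield lab
            return
        g = len(sizes) - len(remaining)
        for combo in itertools.combinations(slots, remaining[0]):
            rest = [s for s in slots if s not in combo]
            for lab in rec(remaining[1:], rest):
                lab[list(combo)] = g
                yield lab

    yield from rec(sizes, list(range(n)))
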