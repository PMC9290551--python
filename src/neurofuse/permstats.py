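"""Cluster-based permutation inference with the max-cluster-mass statistic.

One-sample tests on per-participant effect maps (e.g. Fisher-z b-maps) use
sign-flip permutations: under the symmetric null, negating any subset of
participants' maps leaves the distribution unchanged. Each permutation's
t-map is thresholded at |t| > ``threshold_t`` (strict inequality), connected
components of same-signed suprathreshold bins are formed under the chosen
adjacency (4-connectivity by default), and the maximal absolute cluster
mass (sum of t-values) enters the null distribution. Paired condition
contrasts reduce to the one-sample test on difference maps.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass
class Cluster:
    """A connected set of same-signed suprathreshold bins."""

    bins: np.ndarray          # (extent, ndim) integer coordinates
    mass: float               # signed sum of t-values
    extent: int


@dataclass
class ClusterResult:
    clusters: list
    observed_max_mass: float
    null_max_mass: np.ndarray
    p_value: float
    threshold_t: float
    n_perm: int
    seed: int | None = None
    exact: bool = False

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def _structure(ndim: int, connectivity: int = 1) -> np.ndarray:
    return ndimage.generate_binary_structure(ndim, connectivity)


def find_clusters(stat_map: np.ndarray, threshold: float,
                  connectivity: int = 1) -> list:
    """Connected components of suprathreshold bins of a common sign.

    ``connectivity=1`` is 4-connectivity in 2-D (orthogonal neighbours
    only); ``connectivity=ndim`` includes diagonals. Threshold comparison
    is strict (|t| > threshold). Clusters are returned sorted by
    descending |mass|.
    """
    t = np.asarray(stat_map, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("stat map must be finite")
    struct = _structure(t.ndim, connectivity)
    clusters = []
    for sign in (1.0, -1.0):
        mask = sign * t > threshold
        if not mask.any():
            continue
        labels, n = ndimage.label(mask, structure=struct)
        masses = ndimage.sum_labels(t, labels, index=np.arange(1, n + 1))
        for k in range(n):
            coords = np.argwhere(labels == k + 1)
            clusters.append(Cluster(bins=coords, mass=float(masses[k]),
                                    extent=len(coords)))
    clusters.sort(key=lambda c: -abs(c.mass))
    return clusters


def _max_cluster_mass(tmap: np.ndarray, threshold: float,
                      struct: np.ndarray) -> float:
    best = 0.0
    for sign in (1.0, -1.0):
        mask = sign * tmap > threshold
        if not mask.any():
            continue
        labels, n = ndimage.label(mask, structure=struct)
        masses = ndimage.sum_labels(tmap, labels,
                                    index=np.arange(1, n + 1))
        best = max(best, np.abs(masses).max())
    return best


def _tmaps(signs: np.ndarray, flat: np.ndarray, ss: np.ndarray,
           n: int) -> np.ndarray:
    """t-maps for a batch of sign patterns (rows) against flattened maps.

    Sign flipping leaves per-bin sums of squares unchanged, so only the
    mean depends on the pattern.
    """
    m = signs @ flat / n
    var = (ss[None, :] - n * m ** 2) / (n - 1)
    var = np.maximum(var, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / np.sqrt(var / n)
    t[~np.isfinite(t)] = 0.0
    return t


def cluster_onesample_test(maps: np.ndarray, threshold_t: float = 2.0,
                           n_perm: int = 10000, seed: int | None = None,
                           connectivity: int = 1, exact: bool = False,
                           p_mode: str = "plus_one") -> ClusterResult:
    """One-sample sign-flip max-cluster-mass permutation test.

    ``maps``: participants x (map shape). The observed t-map (one-sample t
    per bin) is thresholded at |t| > ``threshold_t`` and clustered; the
    observed statistic is the largest absolute cluster mass. The null is
    built from ``n_perm`` random sign flips (each participant flipped
    independently with probability 1/2), or from all 2^n patterns when
    ``exact``. ``p_mode='plus_one'`` uses (b + 1) / (n_perm + 1);
    ``'literal'`` counts strictly larger null values over n_perm.
    """
    maps = np.asarray(maps, dtype=float)
    n = maps.shape[0]
    if n < 2:
        raise ValueError("need >= 2 participants")
    if n_perm < 100 and not exact:
        warnings.warn("n_perm < 100: p-value resolution is very coarse")
    shape = maps.shape[1:]
    flat = maps.reshape(n, -1)
    ss = np.sum(flat ** 2, axis=0)
    struct = _structure(len(shape), connectivity)

    obs_t = _tmaps(np.ones((1, n)), flat, ss, n)[0].reshape(shape)
    clusters = find_clusters(obs_t, threshold_t, connectivity)
    obs_max = abs(clusters[0].mass) if clusters else 0.0

    if exact:
        if n > 16:
            raise ValueError("exact enumeration limited to n <= 16")
        signs = np.array(list(itertools.product((1.0, -1.0), repeat=n)))
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([1.0, -1.0], size=(n_perm, n))
    null = np.empty(len(signs))
    batch = 256
    for start in range(0, len(signs), batch):
        ts = _tmaps(signs[start:start + batch], flat, ss, n)
        for k, trow in enumerate(ts):
            null[start + k] = _max_cluster_mass(trow.reshape(shape),
                                                threshold_t, struct)

    # tolerance so the identity permutation ties with the observed value
    # despite floating-point noise in the batched t computation
    eps = 1e-8 * (1.0 + abs(obs_max))
    if not clusters:
        p = 1.0
    elif exact:
        p = float(np.mean(null >= obs_max - eps))
    elif p_mode == "plus_one":
        p = (np.sum(null >= obs_max - eps) + 1.0) / (len(null) + 1.0)
    elif p_mode == "literal":
        p = float(np.sum(null > obs_max + eps)) / len(null)
    else:
        raise ValueError(f"unknown p_mode {p_mode!r}")
    return ClusterResult(clusters=clusters, observed_max_mass=obs_max,
                         null_max_mass=null, p_value=float(p),
                         threshold_t=threshold_t, n_perm=len(signs),
                         seed=seed, exact=exact)


def cluster_condition_test(cond_a: np.ndarray, cond_b: np.ndarray,
                           threshold_t: float = 2.0, n_perm: int = 10000,
                           seed: int | None = None, connectivity: int = 1,
                           exact: bool = False,
                           p_mode: str = "plus_one") -> ClusterResult:
    """Paired-condition cluster permutation test.

    ``cond_a``/``cond_b``: participants x (map shape), already restricted
    to the bins of interest (see ``neurofuse.tf.select_bins``). In a paired
    design, permuting condition labels within participants is equivalent to
    flipping the sign of the difference maps, so this delegates to
    :func:`cluster_onesample_test` on ``cond_a - cond_b``.
    """
    a, b = np.asarray(cond_a, float), np.asarray(cond_b, float)
    if a.shape != b.shape:
        raise ValueError("paired condition arrays must share shape")
    return cluster_onesample_test(a - b, threshold_t=threshold_t,
                                  n_perm=n_perm, seed=seed,
                                  connectivity=connectivity, exact=exact,
                                  p_mode=p_mode)
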