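"""Partition-agreement metrics and expression-state diversity statistics.

Homogeneity and completeness are the entropy-based V-measure components:
with ``C`` the reference classes and ``K`` the test clusters,

    homogeneity  = 1 - H(C|K) / H(C)      (1 if H(C) = 0)
    completeness = 1 - H(K|C) / H(K)      (1 if H(K) = 0)

entropies in nats from the joint contingency table (the base cancels in the
ratios).  Homogeneity is 1 when every test cluster is pure with respect to
the reference; completeness is 1 when every reference class lands in a
single test cluster.  The all-singletons partition has homogeneity 1 (and
low completeness); the one-cluster partition has completeness 1 (and
homogeneity 0 against any multi-class reference).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import DataError, Partition

__all__ = [
    "AgreementReport",
    "DiversityReport",
    "homogeneity_completeness",
    "diversity",
    "composition_table",
]


@dataclass
class AgreementReport:
    homogeneity: float
    completeness: float
    contingency: np.ndarray  # reference classes x test clusters
    H_C: float
    H_K: float
    H_C_given_K: float
    H_K_given_C: float

    def as_dict(self) -> dict:
        return {
            "homogeneity": self.homogeneity,
            "completeness": self.completeness,
            "H_C": self.H_C,
            "H_K": self.H_K,
            "H_C_given_K": self.H_C_given_K,
            "H_K_given_C": self.H_K_given_C,
        }


@dataclass
class DiversityReport:
    """Summary of the cellstate-abundance distribution ``f_s = size_s / n``."""

    n_cellstates: int
    n_cells: int
    n_singlets: int
    singlet_fraction: float
    mean_abundance: float
    median_abundance: float
    entropy: float
    rank_abundance: np.ndarray  # f_s sorted descending

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "n_cellstates", "n_cells", "n_singlets", "singlet_fraction",
            "mean_abundance", "median_abundance", "entropy")}
        d["rank_abundance"] = self.rank_abundance.tolist()
        return d


def _labels(p) -> np.ndarray:
    if isinstance(p, Partition):
        return p.assignment
    return np.asarray(p)


def _entropy(counts: np.ndarray) -> float:
    n = counts.sum()
    p = counts[counts > 0] / n
    return float(-(p * np.log(p)).sum())


def homogeneity_completeness(test, reference) -> AgreementReport:
    """Agreement of a ``test`` partition with a ``reference`` partition.

    Both arguments may be :class:`Partition` objects or label arrays over
    the same cells, in the same cell order.
    """
    kt, kr = _labels(test), _labels(reference)
    if kt.size != kr.size:
        raise DataError(
            f"partitions cover different cell sets: {kt.size} vs {kr.size} cells"
        )
    if (
        isinstance(test, Partition)
        and isinstance(reference, Partition)
        and not np.array_equal(test.matrix.cell_ids, reference.matrix.cell_ids)
    ):
        a = set(test.matrix.cell_ids) ^ set(reference.matrix.cell_ids)
        raise DataError(f"partitions cover different cells: {sorted(a)[:10]}")

    _, kt = np.unique(kt, return_inverse=True)
    _, kr = np.unique(kr, return_inverse=True)
    n_r, n_t = kr.max() + 1, kt.max() + 1
    cont = np.zeros((n_r, n_t), dtype=np.int64)
    np.add.at(cont, (kr, kt), 1)

    n = kt.size
    H_C = _entropy(cont.sum(axis=1))
    H_K = _entropy(cont.sum(axis=0))
    # conditional entropies from the joint table
    p = cont / n
    pk = cont.sum(axis=0) / n
    pc = cont.sum(axis=1) / n
    nz = cont > 0
    H_C_given_K = float(-np.sum(p[nz] * (np.log(p[nz]) - np.log(pk[None, :].repeat(n_r, 0)[nz]))))
    H_K_given_C = float(-np.sum(p[nz] * (np.log(p[nz]) - np.log(pc[:, None].repeat(n_t, 1)[nz]))))

    hom = 1.0 if H_C == 0 else 1.0 - H_C_given_K / H_C
    com = 1.0 if H_K == 0 else 1.0 - H_K_given_C / H_K
    return AgreementReport(float(hom), float(com), cont, H_C, H_K,
                           H_C_given_K, H_K_given_C)


def diversity(partition: Partition) -> DiversityReport:
    """Diversity statistics of the cellstate-abundance distribution."""
    sizes = np.sort(partition.cluster_sizes)[::-1]
    n = int(sizes.sum())
    f = sizes / n
    n_singlets_cells = int(sizes[sizes == 1].sum())
    return DiversityReport(
        n_cellstates=int(sizes.size),
        n_cells=n,
        n_singlets=int((sizes == 1).sum()),
        singlet_fraction=n_singlets_cells / n,
        mean_abundance=float(f.mean()),
        median_abundance=float(np.median(f)),
        entropy=_entropy(sizes),
        rank_abundance=f,
    )


def composition_table(partition: Partition, annotation) -> pd.DataFrame:
    """Cellstate x annotation-label contingency table.

    ``annotation`` maps cell index (or cell id) to a label; uncovered cells
    fall into an ``"NA"`` bucket.  The result has one row per cellstate with
    raw counts, plus matching ``frac_<label>`` columns with row-normalised
    fractions; row count sums equal cluster sizes.
    """
    n = partition.n_cells
    labels = []
    for c in range(n):
        lab = None
        if isinstance(annotation, dict):
            lab = annotation.get(c, annotation.get(partition.matrix.cell_ids[c]))
        else:
            lab = annotation[c] if c < len(annotation) else None
        labels.append("NA" if lab is None or (isinstance(lab, float) and np.isnan(lab)) else lab)
    df = pd.DataFrame({
        "cellstate": [partition.labels[k] for k in partition.assignment],
        "annotation": labels,
    })
    counts = pd.crosstab(df["cellstate"], df["annotation"])
    fracs = counts.div(counts.sum(axis=1), axis=0)
    fracs.columns = [f"frac_{c}" for c in fracs.columns]
    return pd.concat([counts, fracs], axis=1)
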