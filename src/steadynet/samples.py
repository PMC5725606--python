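"""Steady-state sample tables.

A :class:`SampleSet` holds an Omega x N matrix of absolute abundances, one row
per steady-state sample and one column per taxon.  A zero entry means the
taxon is absent from that sample; the set of taxa present in a sample is its
*support* (the sample's taxa collection).  All inference in this package
consumes these objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SampleSet", "read_samples", "average_replicates"]

#: abundances below this count as "absent" unless the caller overrides it
DEFAULT_ZERO_TOL = 1e-8


@dataclass
class SampleSet:
    """Cross-sectional steady-state abundance samples.

    Parameters
    ----------
    abundances
        ``(n_samples, n_taxa)`` array of non-negative absolute abundances.
    taxon_ids, sample_ids
        Optional labels; generated automatically when omitted.
    zero_tol
        Abundances at or below this threshold are treated as zero when
        deriving supports.
    """

    abundances: np.ndarray
    taxon_ids: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)
    zero_tol: float = DEFAULT_ZERO_TOL

    def __post_init__(self) -> None:
        self.abundances = np.atleast_2d(np.asarray(self.abundances, dtype=float))
        n_samples, n_taxa = self.abundances.shape
        if n_taxa < 2:
            raise ValueError("a SampleSet needs at least two taxa")
        if n_samples < 1:
            raise ValueError("a SampleSet needs at least one sample")
        if np.any(self.abundances < 0):
            raise ValueError("abundances must be non-negative")
        if not np.all(np.isfinite(self.abundances)):
            raise ValueError("abundances must be finite")
        if not self.taxon_ids:
            self.taxon_ids = [f"taxon_{j + 1}" for j in range(n_taxa)]
        if not self.sample_ids:
            self.sample_ids = [f"sample_{k + 1}" for k in range(n_samples)]
        if len(self.taxon_ids) != n_taxa or len(self.sample_ids) != n_samples:
            raise ValueError("label lengths do not match the abundance matrix")

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.abundances.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.abundances.shape[1]

    @property
    def supports(self) -> list[frozenset[int]]:
        """Per-sample support sets: taxa with abundance above ``zero_tol``."""
        present = self.abundances > self.zero_tol
        return [frozenset(np.flatnonzero(row)) for row in present]

    def samples_with_taxon(self, taxon: int) -> np.ndarray:
        """Rows of all samples whose support contains ``taxon``."""
        mask = self.abundances[:, taxon] > self.zero_tol
        return self.abundances[mask]

    # ------------------------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.abundances, index=self.sample_ids, columns=self.taxon_ids
        )

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, zero_tol: float = DEFAULT_ZERO_TOL
    ) -> "SampleSet":
        return cls(
            abundances=df.to_numpy(dtype=float),
            taxon_ids=[str(c) for c in df.columns],
            sample_ids=[str(i) for i in df.index],
            zero_tol=zero_tol,
        )


def average_replicates(samples: SampleSet) -> SampleSet:
    """Collapse samples sharing an identical support to their arithmetic mean.

    Replicate steady states measured on the same taxa collection are averaged
    per taxon to a single representative sample; sample order follows first
    occurrence of each support.
    """
    groups: dict[frozenset[int], list[int]] = {}
    for k, supp in enumerate(samples.supports):
        groups.setdefault(supp, []).append(k)
    rows, ids = [], []
    for supp, members in groups.items():
        rows.append(samples.abundances[members].mean(axis=0))
        ids.append(samples.sample_ids[members[0]])
    return SampleSet(
        abundances=np.array(rows),
        taxon_ids=list(samples.taxon_ids),
        sample_ids=ids,
        zero_tol=samples.zero_tol,
    )


def read_samples(
    path,
    sep: str = "\t",
    zero_tol: float = DEFAULT_ZERO_TOL,
    average: bool = True,
    transpose: bool = False,
) -> SampleSet:
    """Read a delimited sample table.

    The expected layout is samples in rows, taxa in columns, a header row of
    taxon names and the first column holding sample identifiers
    (``transpose=True`` accepts the taxa-in-rows layout).  Replicates with
    identical supports are averaged unless ``average=False``.
    """
    df = pd.read_csv(path, sep=sep, index_col=0)
    if transpose:
        df = df.T
    try:
        df = df.astype(float)
    except ValueError as exc:  # non-numeric cell
        raise ValueError(f"non-numeric abundance in {path}: {exc}") from exc
    ss = SampleSet.from_dataframe(df, zero_tol=zero_tol)
    return average_replicates(ss) if average else ss
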