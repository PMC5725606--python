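"""Readers, writers, and run configuration.

All tabular output is plain TSV; every run also writes a JSON manifest with
the configuration, seed, and package version so results can be reproduced
byte-for-byte.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .glv import GLVParameters
from .heuristic import InferenceReport
from .signs import SignMatrix

__all__ = [
    "RunConfig",
    "read_prior",
    "write_sign_matrix",
    "write_glv",
    "read_sign_matrix",
]


@dataclass
class RunConfig:
    """Serializable configuration of a run (echoed in output manifests)."""

    seed: int | None = None
    zero_tol: float = 1e-8
    psi: int | None = None
    q: float | None = None
    eta: float = 0.0
    method: str = "heuristic"
    extra: dict = field(default_factory=dict)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def read_prior(path, sep: str = "\t") -> dict[tuple[int, int], int]:
    """Read known interaction signs: three columns (taxon_i, taxon_j, sign).

    Taxon indices are 0-based integers; sign must be one of {-1, 0, 1}.
    """
    df = pd.read_csv(path, sep=sep, header=None, comment="#")
    if df.shape[1] != 3:
        raise ValueError("prior file must have exactly three columns")
    priors: dict[tuple[int, int], int] = {}
    for _, (i, j, s) in df.iterrows():
        s = int(s)
        if s not in (-1, 0, 1):
            raise ValueError(f"invalid prior sign {s} for ({i}, {j})")
        priors[(int(i), int(j))] = s
    return priors


def _manifest(prefix: Path, config: RunConfig | None, extra: dict) -> None:
    manifest = {
        "package": "steadynet",
        "version": __version__,
        "config": asdict(config) if config else None,
        **extra,
    }
    (prefix.parent / f"{prefix.name}.manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str)
    )


def write_sign_matrix(
    signs: SignMatrix,
    prefix,
    report: InferenceReport | None = None,
    config: RunConfig | None = None,
) -> None:
    """Write ``<prefix>.signs.tsv`` (NA marks undetermined), edge list, manifest."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    signs.to_dataframe().to_csv(f"{prefix}.signs.tsv", sep="\t")
    edges = []
    for i in range(signs.n_taxa):
        for j in range(signs.n_taxa):
            if signs.determined[i, j] and signs.values[i, j] != 0:
                edges.append(
                    (signs.taxon_ids[i], signs.taxon_ids[j], int(signs.values[i, j]))
                )
    pd.DataFrame(edges, columns=["taxon_i", "taxon_j", "sign"]).to_csv(
        f"{prefix}.edges.tsv", sep="\t", index=False
    )
    _manifest(prefix, config, {"report": report.to_dict() if report else None})


def write_glv(
    params: GLVParameters,
    prefix,
    taxon_ids: list[str] | None = None,
    config: RunConfig | None = None,
) -> None:
    """Write ``A.tsv``, ``r.tsv``, an edge list, and a diagnostics manifest."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n = params.n_taxa
    ids = taxon_ids or [f"taxon_{j + 1}" for j in range(n)]
    pd.DataFrame(params.A, index=ids, columns=ids).to_csv(
        f"{prefix}.A.tsv", sep="\t"
    )
    pd.Series(params.r, index=ids, name="growth_rate").to_csv(
        f"{prefix}.r.tsv", sep="\t"
    )
    edges = []
    for i in range(n):
        selected = {
            j
            for d in params.diagnostics
            if d.taxon == i and d.selected_support
            for j in d.selected_support
        }
        for j in range(n):
            if i != j and abs(params.A[i, j]) > 0:
                edges.append((ids[i], ids[j], params.A[i, j], j in selected))
    pd.DataFrame(
        edges, columns=["taxon_i", "taxon_j", "a_ij", "knockoff_selected"]
    ).to_csv(f"{prefix}.edges.tsv", sep="\t", index=False)
    _manifest(
        prefix,
        config,
        {"diagnostics": [asdict(d) for d in params.diagnostics]},
    )


def read_sign_matrix(path, sep: str = "\t") -> SignMatrix:
    """Read a sign matrix TSV written by :func:`write_sign_matrix`."""
    df = pd.read_csv(path, sep=sep, index_col=0, keep_default_na=False)
    raw = df.to_numpy(dtype=object)
    undet = np.array(
        [[str(v).strip() == "NA" for v in row] for row in raw], dtype=bool
    )
    values = np.where(undet, 0, raw).astype(np.int8)
    return SignMatrix(
        values=values, determined=~undet, taxon_ids=[str(c) for c in df.columns]
    )
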