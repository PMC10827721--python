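"""File formats and pipeline configuration.

Plain-text formats throughout: counts as TSV (first column ``gene_id``),
design as CSV, gene sets as one id per line, networks as edge-list TSV
and GraphML, reports as JSON. All writes are atomic (temp file +
rename). Gene and sample order is canonicalized lexicographically on
load so downstream outputs are order-stable.
"""

from __future__ import annotations

import json
import os
import tempfile
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .diffexpr import GeneSet
from .synthetic import CountMatrix, validate_design

__all__ = [
    "PipelineConfig",
    "read_design",
    "read_counts",
    "write_counts",
    "write_design",
    "read_gene_set",
    "write_gene_set",
    "write_edge_list",
    "write_graphml",
    "write_json",
    "atomic_write_text",
]


def atomic_write_text(path: str | Path, text: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def write_json(path: str | Path, obj) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    atomic_write_text(path, json.dumps(obj, indent=1, sort_keys=True, default=default))


def read_design(path: str | Path) -> pd.DataFrame:
    design = pd.read_csv(path)
    validate_design(design)
    return design.sort_values("sample_id", kind="stable").reset_index(drop=True)


def read_counts(path: str | Path, design: pd.DataFrame) -> CountMatrix:
    """Load a gene x sample count TSV and validate it against a design.

    Errors are specific: duplicate gene ids, non-integer counts, count
    columns absent from the design (and vice versa) each name the
    offender.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.columns[0] != "gene_id":
        raise ValueError("first column of a counts TSV must be 'gene_id'")
    df = df.set_index("gene_id")
    dup = df.index[df.index.duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"duplicate gene ids: {dup[:5]}")
    design_ids = set(design["sample_id"])
    extra = [c for c in df.columns if c not in design_ids]
    if extra:
        raise ValueError(f"count column(s) absent from design: {extra}")
    missing = sorted(design_ids - set(df.columns))
    if missing:
        raise ValueError(f"design sample(s) missing from counts: {missing}")
    vals = df.to_numpy()
    if not np.issubdtype(vals.dtype, np.integer):
        as_float = df.to_numpy(dtype=float)
        if not np.allclose(as_float, np.round(as_float)):
            bad = np.argwhere(as_float != np.round(as_float))[0]
            raise ValueError(
                f"non-integer count at gene {df.index[bad[0]]!r}, sample {df.columns[bad[1]]!r}"
            )
        df = df.round().astype(np.int64)
    # canonical order: genes and samples lexicographic
    design = design.sort_values("sample_id", kind="stable").reset_index(drop=True)
    df = df.sort_index().loc[:, design["sample_id"].tolist()]
    return CountMatrix(df, design)


def write_counts(path: str | Path, cm: CountMatrix) -> None:
    atomic_write_text(path, cm.counts.rename_axis("gene_id").to_csv(sep="\t"))


def write_design(path: str | Path, design: pd.DataFrame) -> None:
    atomic_write_text(path, design.to_csv(index=False))


def read_gene_set(path: str | Path, label: str | None = None, direction: str = "any") -> GeneSet:
    genes = frozenset(
        line.strip() for line in Path(path).read_text().splitlines() if line.strip()
    )
    return GeneSet(label or Path(path).stem, genes, direction)


def write_gene_set(path: str | Path, gs: GeneSet) -> None:
    atomic_write_text(path, "\n".join(sorted(gs.genes)) + "\n")


def write_edge_list(path: str | Path, net: nx.Graph) -> None:
    lines = ["gene_a\tgene_b\trho\tp\tq"]
    for u, v, d in sorted(net.edges(data=True), key=lambda e: (str(e[0]), str(e[1]))):
        a, b = sorted((str(u), str(v)))
        lines.append(
            f"{a}\t{b}\t{d.get('rho', float('nan')):.6g}\t"
            f"{d.get('p', float('nan')):.6g}\t{d.get('q', float('nan')):.6g}"
        )
    atomic_write_text(path, "\n".join(lines) + "\n")


def write_graphml(path: str | Path, net: nx.Graph) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tmp = path.with_name(f".{path.name}.tmp")
    nx.write_graphml(net, tmp)
    os.replace(tmp, path)


@dataclass
class PipelineConfig:
    """End-to-end run configuration.

    Threshold defaults are the analysis' canonical values: DE cutoffs
    FDR < 0.001 and |logFC| > 1.5; network thresholds FDR = 0.001 and
    rho_s = 0.8; communities of at least 100 nodes; top-50 hubs per
    community; walk length 4.
    """

    output_dir: str = "coexnet_run"
    mode: str = "synthetic"  # "synthetic" | "user-data"
    counts_path: str | None = None
    design_path: str | None = None
    annotation_path: str | None = None
    de_fdr: float = 0.001
    de_lfc: float = 1.5
    net_fdr: float = 0.001
    rho_min: float = 0.8
    use_abs: bool = True
    min_community: int = 100
    hub_k: int = 50
    walktrap_t: int = 4
    baseline_repeats: int = 20
    seed: int = 0
    generator: dict = field(default_factory=dict)  # GeneratorParams overrides

    def __post_init__(self) -> None:
        for name in ("de_fdr", "de_lfc", "net_fdr", "rho_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.min_community < 1 or self.hub_k < 1 or self.walktrap_t < 1:
            raise ValueError("min_community, hub_k and walktrap_t must be >= 1")
        if self.mode not in ("synthetic", "user-data"):
            raise ValueError("mode must be 'synthetic' or 'user-data'")
        if self.mode == "user-data" and not (self.counts_path and self.design_path):
            raise ValueError("user-data mode needs counts_path and design_path")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        atomic_write_text(path, yaml.safe_dump(asdict(self), sort_keys=True))
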