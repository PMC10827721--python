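"""Synthetic RNA-seq count data with planted structure.

Generates negative-binomial count matrices for a factorial design
(conditions x timepoints x replicates) with three kinds of planted signal:

* **differential expression** — a subset of genes carries a known log2
  fold change in one or both treatment arms;
* **co-expression modules** — genes in a module share a latent Gaussian
  factor on the log-mean, so their counts are rank-correlated with a
  strength controlled by a single loading ``lambda``;
* **hub genes** — designated module members get an elevated loading, so
  they correlate more strongly with every other module member and emerge
  as high-connectivity nodes once a network is inferred downstream.

Because the ground truth (module membership, DE genes with signed
effects, hub identities) is returned alongside the counts, every
downstream stage of the pipeline can be validated without external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

CONDITIONS = ("control", "treatA", "treatB")
TIMEPOINTS = (48, 72, 96)

__all__ = [
    "CONDITIONS",
    "TIMEPOINTS",
    "GeneratorParams",
    "GroundTruth",
    "CountMatrix",
    "make_design",
    "simulate_experiment",
]


def make_design(
    n_reps: int = 3,
    timepoints: Sequence[int] = TIMEPOINTS,
    conditions: Sequence[str] = CONDITIONS,
) -> pd.DataFrame:
    """Full-factorial sample design as a DataFrame.

    Columns: ``sample_id`` (``<cond>_<tp>_r<rep>``), ``condition``,
    ``timepoint`` (hours), ``replicate``. The default 3 conditions x
    3 timepoints x 3 replicates gives 27 libraries.

    Raises
    ------
    ValueError
        If ``n_reps < 2`` (within-group dispersion would be undefined
        downstream) or either factor list is empty.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2 (dispersion estimation needs replicates)")
    if not list(timepoints) or not list(conditions):
        raise ValueError("timepoints and conditions must be non-empty")
    rows = [
        {
            "sample_id": f"{cond}_{tp}_r{rep}",
            "condition": cond,
            "timepoint": int(tp),
            "replicate": rep,
        }
        for cond in conditions
        for tp in timepoints
        for rep in range(1, n_reps + 1)
    ]
    design = pd.DataFrame(rows)
    if design["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in design")
    return design


def validate_design(design: pd.DataFrame) -> None:
    """Check design invariants: required columns, unique sample ids,
    >=2 replicates per (condition, timepoint) cell."""
    required = {"sample_id", "condition", "timepoint", "replicate"}
    missing = required - set(design.columns)
    if missing:
        raise ValueError(f"design is missing columns: {sorted(missing)}")
    if design["sample_id"].duplicated().any():
        dups = design.loc[design["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids: {dups}")
    cell_sizes = design.groupby(["condition", "timepoint"], observed=True).size()
    if (cell_sizes < 2).any():
        bad = cell_sizes[cell_sizes < 2].index.tolist()
        raise ValueError(f"(condition, timepoint) cells with <2 replicates: {bad}")


@dataclass(frozen=True)
class GeneratorParams:
    """Knobs of the count simulator.

    Parameters
    ----------
    n_genes : total genes simulated.
    module_sizes : sizes of planted co-expression modules (each >= 2,
        sum <= n_genes); module genes occupy the first gene slots.
    module_loading : latent-factor loading ``lambda`` in [0, 1] shared by
        non-hub module genes. 0 disables planted correlation.
    hub_per_module : planted hubs per module; hubs use ``hub_loading``.
    hub_loading : loading for hubs, must be >= module_loading.
    de_fraction : fraction of genes carrying true differential expression.
    de_logfc : |log2 fold change| of planted DE genes (> 0).
    baseline_logmean_mean, baseline_logmean_sd : natural-log mean
        expression is drawn per gene from this Normal; the defaults put
        the median expected count near exp(5) ~ 150.
    dispersion : NB dispersion phi, variance = mu + phi * mu^2; the
        default 0.04 is a biological CV of 0.2, typical of isogenic
        plant lines under controlled conditions.
    libsize_range : per-library relative depth, Uniform on this interval.
    seed : RNG seed; same seed gives bit-identical output.
    """

    n_genes: int = 2000
    module_sizes: tuple[int, ...] = (120, 120, 120)
    module_loading: float = 0.8
    hub_per_module: int = 5
    hub_loading: float = 0.95
    de_fraction: float = 0.25
    de_logfc: float = 2.0
    baseline_logmean_mean: float = 5.0
    baseline_logmean_sd: float = 1.0
    dispersion: float = 0.04
    libsize_range: tuple[float, float] = (0.7, 1.3)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if any(s < 2 for s in self.module_sizes):
            raise ValueError("module sizes must each be >= 2")
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError("sum(module_sizes) exceeds n_genes")
        if not 0.0 <= self.module_loading <= 1.0:
            raise ValueError("module_loading must be in [0, 1]")
        if self.hub_per_module < 0:
            raise ValueError("hub_per_module must be >= 0")
        if self.hub_loading < self.module_loading:
            raise ValueError("hub_loading must be >= module_loading")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must be in [0, 1]")
        if self.de_logfc <= 0:
            raise ValueError("de_logfc must be > 0")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        lo, hi = self.libsize_range
        if not (0 < lo <= hi):
            raise ValueError("libsize_range must be positive with lo <= hi")


@dataclass
class GroundTruth:
    """Planted structure of a simulated experiment.

    ``de_genes`` maps gene -> {arm: signed log2FC} where arm is a treated
    condition name; a gene DE in both arms has two entries.
    """

    module_of: dict[str, str]
    de_genes: dict[str, dict[str, float]]
    hub_genes: dict[str, list[str]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(**d)


@dataclass
class CountMatrix:
    """Integer gene x sample counts with the matching sample design.

    ``counts`` is a DataFrame indexed by gene id with one column per
    sample, aligned to ``design['sample_id']``.
    """

    counts: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        validate_design(self.design)
        if list(self.counts.columns) != list(self.design["sample_id"]):
            raise ValueError("count columns do not match design sample ids")
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate gene ids")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            raise ValueError("counts must be integers")
        if (vals < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        keep = [s for s in self.samples if s in set(sample_ids)]
        design = self.design[self.design["sample_id"].isin(keep)].reset_index(drop=True)
        return CountMatrix(self.counts[design["sample_id"].tolist()], design)


def _assign_modules(params: GeneratorParams, genes: list[str]):
    module_of: dict[str, str] = {}
    hub_genes: dict[str, list[str]] = {}
    loadings = np.zeros(params.n_genes)
    start = 0
    for m, size in enumerate(params.module_sizes, start=1):
        label = f"M{m}"
        members = genes[start : start + size]
        for g in members:
            module_of[g] = label
        hubs = members[: params.hub_per_module]
        hub_genes[label] = list(hubs)
        loadings[start : start + size] = params.module_loading
        loadings[start : start + len(hubs)] = params.hub_loading
        start += size
    return module_of, hub_genes, loadings


def _assign_de(
    params: GeneratorParams, genes: list[str], n_module: int, rng: np.random.Generator
) -> dict[str, dict[str, float]]:
    # Module genes first: downstream networks are built on DE-filtered
    # genes, so planting DE on the modules keeps them in the network.
    n_de = round(params.de_fraction * params.n_genes)
    candidates = list(genes[:n_module])
    background = list(genes[n_module:])
    if n_de > len(candidates):
        extra = rng.choice(len(background), size=n_de - len(candidates), replace=False)
        candidates += [background[i] for i in sorted(extra)]
    de_list = candidates[:n_de]
    arms = rng.integers(0, 3, size=n_de)  # 0 -> A only, 1 -> B only, 2 -> both
    signs = rng.choice([-1.0, 1.0], size=n_de)
    de_genes: dict[str, dict[str, float]] = {}
    for g, arm, sign in zip(de_list, arms, signs):
        lfc = float(sign * params.de_logfc)
        targets = {0: ("treatA",), 1: ("treatB",), 2: ("treatA", "treatB")}[int(arm)]
        de_genes[g] = {cond: lfc for cond in targets}
    return de_genes


def simulate_experiment(
    design: pd.DataFrame, params: GeneratorParams
) -> tuple[CountMatrix, GroundTruth]:
    """Draw a count matrix with planted DE, modules, and hubs.

    The per-gene, per-sample natural-log mean is

    ``log mu = b_g + lambda_g * z_{m(g), s} + sign_g * de_logfc * ln2 * [DE hit]``

    with ``b_g ~ N(baseline_logmean_mean, sd)`` and one standard-normal
    factor ``z`` per (module, sample). Counts are drawn from a negative
    binomial with mean ``L_s * exp(log mu)`` and dispersion ``phi``
    (``L_s ~ Uniform(libsize_range)``). DE shifts apply at every
    timepoint of the gene's treated arm(s). Deterministic per seed.
    """
    validate_design(design)
    rng = np.random.default_rng(params.seed)
    n_genes, n_samples = params.n_genes, len(design)
    width = max(4, len(str(n_genes)))
    genes = [f"g{i:0{width}d}" for i in range(1, n_genes + 1)]

    module_of, hub_genes, loadings = _assign_modules(params, genes)
    n_module = sum(params.module_sizes)
    de_genes = _assign_de(params, genes, n_module, rng)

    baseline = rng.normal(
        params.baseline_logmean_mean, params.baseline_logmean_sd, size=n_genes
    )
    n_modules = len(params.module_sizes)
    z = rng.normal(size=(n_modules, n_samples))  # shared factor per module x sample

    log_mu = np.tile(baseline[:, None], (1, n_samples))
    start = 0
    for m, size in enumerate(params.module_sizes):
        block = slice(start, start + size)
        log_mu[block, :] += loadings[block, None] * z[m][None, :]
        start += size

    gene_pos = {g: i for i, g in enumerate(genes)}
    cond = design["condition"].to_numpy()
    for g, per_arm in de_genes.items():
        for arm, lfc in per_arm.items():
            mask = cond == arm
            log_mu[gene_pos[g], mask] += lfc * np.log(2.0)

    lib = rng.uniform(*params.libsize_range, size=n_samples)
    mu = lib[None, :] * np.exp(log_mu)
    phi = params.dispersion
    if phi < 1e-8:
        counts = rng.poisson(mu)
    else:
        # NB(mean mu, var mu + phi mu^2) == numpy NB(n = 1/phi, p = 1/(1 + phi mu))
        counts = rng.negative_binomial(1.0 / phi, 1.0 / (1.0 + phi * mu))

    cm = CountMatrix(
        pd.DataFrame(
            counts.astype(np.int64), index=genes, columns=design["sample_id"].tolist()
        ),
        design.reset_index(drop=True),
    )
    truth = GroundTruth(module_of=module_of, de_genes=de_genes, hub_genes=hub_genes)
    return cm, truth
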