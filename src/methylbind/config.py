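"""Simulation configuration.

:class:`SimulationConfig` bundles every knob of the synthetic-data module.
The defaults are the study conditions used throughout the test suite and the
acceptance workflows: a 6 Mb genome at 10x bisulfite coverage, near-bimodal
CG methylation with sparse high-mCAC sites, 15,000 genes with lognormal
lengths tuned so per-gene log10 mCG and log10 mCAC correlate at r ~ 0.9,
multiplicative cut-site depletion of depth 0.5 over a +/-25 bp core at bound
methylated sites, and 2 million cut sites per replicate, three replicates
per genotype.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

from .errors import InvalidConfigurationError

#: Methylation contexts recognized throughout the package.  CA is refined to
#: the trinucleotide; CT and CC stay dinucleotide catch-alls.
CONTEXTS = ("CG", "CAC", "CAT", "CAG", "CAA", "CT", "CC")


@dataclass(frozen=True)
class BetaMixture:
    """Two-component beta mixture for true per-site methylation levels.

    ``high`` and ``low`` are the modes of the two components, ``weight`` the
    probability of the high component.  ``concentration`` controls spread
    (a component with mode m is Beta(1 + c*m, 1 + c*(1-m)); modes of exactly
    0 or 1 collapse to point masses).
    """

    high: float
    low: float
    weight: float
    concentration: float = 30.0

    def __post_init__(self) -> None:
        for name in ("high", "low", "weight"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidConfigurationError(
                    f"BetaMixture.{name}={v!r} outside [0, 1]"
                )
        if self.concentration <= 0:
            raise InvalidConfigurationError("concentration must be positive")

    @property
    def mean_mode(self) -> float:
        """Mixture mean under the point-mode approximation."""
        return self.weight * self.high + (1.0 - self.weight) * self.low


def default_context_meth_params() -> dict[str, BetaMixture]:
    """Per-context methylation mixtures.

    CG is near-bimodal and mostly high; CA trinucleotides are sparse and low
    with a small hypermethylated component; CT/CC are nearly unmethylated.
    The CAC high-component weight (0.10) is enriched relative to brain
    genomes so that desk-scale genomes still yield catalog-sized sets of
    >=75%-methylated CAC sites.
    """
    return {
        "CG": BetaMixture(high=0.95, low=0.03, weight=0.80),
        "CAC": BetaMixture(high=0.90, low=0.02, weight=0.10),
        "CAT": BetaMixture(high=0.85, low=0.02, weight=0.06),
        "CAG": BetaMixture(high=0.85, low=0.02, weight=0.04),
        "CAA": BetaMixture(high=0.85, low=0.02, weight=0.03),
        "CT": BetaMixture(high=0.80, low=0.01, weight=0.02),
        "CC": BetaMixture(high=0.80, low=0.01, weight=0.01),
    }


def default_effect_sizes() -> dict[str, tuple[float, float]]:
    """(beta_CG, beta_CAC) in log2FC units per log10 binding-site unit.

    The null-mutant contrast carries both motif effects; the mCG-only-binder
    contrast loses the mCG effect while keeping the mCAC one.
    """
    return {"KO/WT": (0.2, 0.3), "MM2/WT": (0.0, 0.3)}


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0

    # genome
    genome_length: int = 6_000_000
    n_chromosomes: int = 2
    gc_fraction: float = 0.42

    # WGBS
    coverage_mean: float = 10.0
    context_meth_params: dict[str, BetaMixture] = field(
        default_factory=default_context_meth_params
    )

    # genes: lognormal length law plus per-gene, per-motif density
    # dispersion; together these set the mCG/mCAC collinearity.
    n_genes: int = 15_000
    gene_length_mu: float = math.log(20_000.0)
    gene_length_sigma: float = 0.5
    mcg_per_base: float = 0.015
    mcac_per_base: float = 0.005
    density_log_sd: float = 0.15

    # expression
    effect_sizes: dict[str, tuple[float, float]] = field(
        default_factory=default_effect_sizes
    )
    noise_sd: float = 0.3

    # ATAC footprint planting
    footprint_depth: float = 0.5
    footprint_halfwidth: int = 25
    bound_contexts: tuple[str, ...] = ("CG", "CAC")
    library_size: int = 2_000_000
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if self.genome_length <= 0:
            raise InvalidConfigurationError("genome_length must be positive")
        if self.n_chromosomes <= 0:
            raise InvalidConfigurationError("n_chromosomes must be positive")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise InvalidConfigurationError("gc_fraction outside [0, 1]")
        if self.coverage_mean < 0:
            raise InvalidConfigurationError("coverage_mean must be >= 0")
        if not 0.0 <= self.footprint_depth <= 1.0:
            raise InvalidConfigurationError("footprint_depth outside [0, 1]")
        if self.footprint_halfwidth < 0:
            raise InvalidConfigurationError("footprint_halfwidth must be >= 0")
        if self.noise_sd < 0:
            raise InvalidConfigurationError("noise_sd must be >= 0")
        if self.library_size <= 0 or self.n_replicates <= 0:
            raise InvalidConfigurationError(
                "library_size and n_replicates must be positive"
            )
        for ctx in self.context_meth_params:
            if ctx not in CONTEXTS:
                raise InvalidConfigurationError(f"unknown context {ctx!r}")

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["context_meth_params"] = {
            k: dataclasses.asdict(v) for k, v in self.context_meth_params.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "context_meth_params" in d:
            d["context_meth_params"] = {
                k: v if isinstance(v, BetaMixture) else BetaMixture(**v)
                for k, v in d["context_meth_params"].items()
            }
        if "effect_sizes" in d:
            d["effect_sizes"] = {
                k: tuple(v) for k, v in d["effect_sizes"].items()
            }
        if "bound_contexts" in d:
            d["bound_contexts"] = tuple(d["bound_contexts"])
        return cls(**d)
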