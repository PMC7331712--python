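"""Configuration objects for the synthetic generator, differential calling and CLR inference.

All configs are frozen dataclasses validated on construction so a bad
parameter fails before any computation starts.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class ConfigurationError(ValueError):
    """Raised when a configuration is internally inconsistent or infeasible."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Shape and effect-size parameters of the synthetic multi-omics study.

    The defaults emulate a perturbation study on a single soil community:
    three perturbations (dry, wet, glycine amendment) plus a control, three
    field sites, triplicate microcosms, log2-scale expression of EC-numbered
    gene functions, and a master metabolic reaction network with planted
    condition-specific reaction chains.

    Parameters
    ----------
    seed:
        Root seed; every generator derives an independent stream from it.
    n_genes:
        Total gene functions in the expression matrix (network ECs plus
        uncoupled filler genes).
    conditions:
        Condition labels; ``control`` names the reference condition.
    n_sites, n_replicates:
        Field sites and replicate microcosms per condition x site.
    n_modules, module_size, latent_strength:
        Planted co-expression modules: disjoint gene sets sharing a latent
        per-sample factor with this weight (log2 units per factor s.d.).
    responsive_fold_change:
        Linear fold change of planted condition-responsive genes in their
        own condition versus control.
    noise_sd:
        Replicate noise standard deviation on the log2 scale.
    n_metabolites, n_reactions, mean_reaction_degree:
        Master-network shape; ``mean_reaction_degree`` is the expected
        number of substrate links (and, independently, product links) per
        reaction, each drawn as 1 + Poisson(mean_reaction_degree - 1).
    pathway_length:
        Reactions per planted condition-specific chain (and hence planted
        responsive genes per non-control condition).
    n_core_metabolites:
        Size of the core metabolite pool that is detected (near-)identically
        across conditions.
    metabolite_detection_rate:
        Per-metabolite detection probability for the core pool.
    """

    seed: int = 0
    n_genes: int = 200
    conditions: tuple[str, ...] = ("dry", "wet", "glycine", "control")
    control: str = "control"
    n_sites: int = 3
    n_replicates: int = 3
    n_modules: int = 5
    module_size: int = 10
    latent_strength: float = 2.0
    responsive_fold_change: float = 4.0
    noise_sd: float = 0.5
    n_metabolites: int = 80
    n_reactions: int = 100
    mean_reaction_degree: float = 2.0
    pathway_length: int = 5
    n_core_metabolites: int = 20
    metabolite_detection_rate: float = 0.9

    def __post_init__(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "n_sites": self.n_sites,
            "n_replicates": self.n_replicates,
            "n_modules": self.n_modules,
            "module_size": self.module_size,
            "n_metabolites": self.n_metabolites,
            "n_reactions": self.n_reactions,
            "pathway_length": self.pathway_length,
            "n_core_metabolites": self.n_core_metabolites,
        }
        for name, value in counts.items():
            if value < 1:
                raise ConfigurationError(f"{name} must be positive, got {value}")
        if self.n_modules * self.module_size > self.n_genes:
            raise ConfigurationError(
                "n_modules * module_size exceeds n_genes: "
                f"{self.n_modules} * {self.module_size} > {self.n_genes}"
            )
        if not 0.0 <= self.metabolite_detection_rate <= 1.0:
            raise ConfigurationError(
                f"metabolite_detection_rate must be in [0, 1], got "
                f"{self.metabolite_detection_rate}"
            )
        if self.responsive_fold_change < 1.0:
            raise ConfigurationError("responsive_fold_change must be >= 1")
        if self.noise_sd < 0 or self.latent_strength < 0:
            raise ConfigurationError("noise_sd and latent_strength must be >= 0")
        if self.mean_reaction_degree < 1.0:
            raise ConfigurationError("mean_reaction_degree must be >= 1")
        if self.control not in self.conditions:
            raise ConfigurationError(
                f"control condition {self.control!r} missing from conditions"
            )
        for cond in self.conditions:
            if "_" in cond or not cond:
                raise ConfigurationError(
                    f"condition labels must be non-empty and contain no '_': {cond!r}"
                )

    @property
    def perturbations(self) -> tuple[str, ...]:
        """Non-control conditions, in declared order."""
        return tuple(c for c in self.conditions if c != self.control)


@dataclass(frozen=True)
class DiffExprConfig:
    """Thresholds and method choices for over-expression calling.

    ``fc_threshold`` is a linear fold change (genes pass at
    log2FC >= log2(fc_threshold)); ``q_threshold`` bounds the adjusted
    p-value. Both boundaries are inclusive.
    """

    fc_threshold: float = 2.0
    q_threshold: float = 0.05
    test: str = "welch"
    adjustment: str = "bh"

    def __post_init__(self) -> None:
        if self.fc_threshold <= 1.0:
            raise ConfigurationError("fc_threshold must be > 1")
        if not 0.0 < self.q_threshold <= 1.0:
            raise ConfigurationError("q_threshold must be in (0, 1]")
        if self.test != "welch":
            raise ConfigurationError(f"unknown test {self.test!r}")
        if self.adjustment != "bh":
            raise ConfigurationError(f"unknown adjustment {self.adjustment!r}")


@dataclass(frozen=True)
class ClrConfig:
    """Mutual-information estimation and network selection settings.

    ``z_threshold`` defaults to 4.20, a stringent cutoff whose
    standard-normal upper-tail probability is below 5e-5. ``target_edges``
    switches from thresholding to top-k edge selection when set.
    """

    mi_estimator: str = "bspline"
    n_bins: int = 10
    spline_order: int = 3
    rank_transform: bool = True
    background_mode: str = "per_gene"
    z_threshold: float = 4.20
    target_edges: int | None = None

    def __post_init__(self) -> None:
        if self.mi_estimator not in ("bspline", "equal_width_bins"):
            raise ConfigurationError(f"unknown mi_estimator {self.mi_estimator!r}")
        if self.background_mode not in ("per_gene", "global"):
            raise ConfigurationError(
                f"unknown background_mode {self.background_mode!r}"
            )
        if self.n_bins < 2:
            raise ConfigurationError("n_bins must be >= 2")
        if not 1 <= self.spline_order < self.n_bins:
            raise ConfigurationError("spline_order must satisfy 1 <= order < n_bins")
        if self.z_threshold <= 0:
            raise ConfigurationError("z_threshold must be > 0")
        if self.target_edges is not None and self.target_edges <= 0:
            raise ConfigurationError("target_edges must be positive when set")
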