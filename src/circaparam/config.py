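"""Configuration objects for the simulator and the end-to-end pipeline."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["SimulationConfig", "PipelineConfig"]


def _check_weights(name: str, weights: dict[str, float]) -> None:
    total = sum(weights.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"{name} weights must sum to 1, got {total}")
    if any(w < 0 for w in weights.values()):
        raise ValueError(f"{name} weights must be nonnegative")


@dataclass
class SimulationConfig:
    """Ground-truth generation parameters.

    Defaults emulate the shape of a high-density liver time course (hourly
    sampling over two circadian days, ~10^4 loci with redundant probe sets,
    bimodal log10 intensities separating around 1.45) and a 46-tissue
    compendium; see the methods note for what each knob controls.
    """

    n_loci: int = 10_000
    probes_per_locus_range: tuple[int, int] = (1, 3)
    n_timepoints: int = 48
    sampling_interval: float = 1.0  # hours
    rhythmic_fraction: float = 0.15
    waveform_mix: dict[str, float] = field(
        default_factory=lambda: {"cosine": 0.7, "spike": 0.1, "box": 0.1, "sawtooth": 0.1}
    )
    period_hours: float = 24.0
    phase_window_weights: dict[str, float] = field(
        default_factory=lambda: {"dawn": 0.2, "day": 0.3, "dusk": 0.2, "night": 0.3}
    )
    relative_amplitude_range: tuple[float, float] = (2.0, 5.0)  # peak/trough, linear
    baseline_log10_modes: tuple[float, float] = (0.8, 2.1)  # non-expressed, expressed
    noise_sd: float = 0.05  # log10 units
    n_tissues: int = 46
    n_chromosomes: int = 19
    seed: int = 0
    # annotation / auxiliary structure
    divergent_fraction: float = 0.02  # share of loci placed in head-to-head pairs
    expressed_fraction: float = 0.85  # share of loci expressed in the focal tissue
    ubiquitous_fraction: float = 0.55  # share of genes expressed in all tissues
    general_list_extra_fraction: float = 0.30  # non-rhythmic loci on the general list
    n_mirnas: int = 20

    def __post_init__(self) -> None:
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if self.n_chromosomes < 1:
            raise ValueError("n_chromosomes must be >= 1")
        if self.n_tissues < 1:
            raise ValueError("n_tissues must be >= 1")
        if not 0.0 <= self.rhythmic_fraction <= 1.0:
            raise ValueError("rhythmic_fraction must lie in [0, 1]")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        lo, hi = self.relative_amplitude_range
        if lo < 1 or hi < lo:
            raise ValueError("relative_amplitude_range must be >= 1 and ordered")
        plo, phi = self.probes_per_locus_range
        if plo < 1 or phi < plo:
            raise ValueError("probes_per_locus_range must be >= 1 and ordered")
        _check_weights("waveform_mix", self.waveform_mix)
        _check_weights("phase_window_weights", self.phase_window_weights)
        for frac in ("divergent_fraction", "expressed_fraction", "ubiquitous_fraction",
                     "general_list_extra_fraction"):
            if not 0.0 <= getattr(self, frac) <= 1.0:
                raise ValueError(f"{frac} must lie in [0, 1]")

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        for key in ("probes_per_locus_range", "relative_amplitude_range", "baseline_log10_modes"):
            data[key] = list(data[key])
        Path(path).write_text(yaml.safe_dump({"simulation": data}, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        data = yaml.safe_load(Path(path).read_text())["simulation"]
        for key in ("probes_per_locus_range", "relative_amplitude_range", "baseline_log10_modes"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class PipelineConfig:
    """End-to-end run parameters on top of a simulation (or loaded inputs)."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    q_threshold: float = 0.001
    expression_cutoff: float | None = None  # None = estimate, fall back to 1.45
    periods: tuple[float, ...] = tuple(range(20, 29))
    nmf_rank: int = 3
    nmf_runs: int = 20
    consensus_threshold: float = 0.8
    min_cluster_size: int = 100
    expression_bin_size: int = 300

    def __post_init__(self) -> None:
        if not 0.0 < self.q_threshold < 1.0:
            raise ValueError("q_threshold must lie in (0, 1)")
        if self.nmf_rank < 2:
            raise ValueError("nmf_rank must be >= 2")
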