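"""Simulation configuration shared by every synthetic-data generator.

A single :class:`SimulationConfig` drives the rRNA reference, the
modification truth table, the RiboMethSeq / HydraPsiSeq read simulators and
the small proteome / qPCR / iBAQ / ROI fixtures, so that one seed fixes the
whole synthetic study.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Tuple

import numpy as np
import yaml


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    Attributes
    ----------
    seed:
        Master seed; every generator derives its own independent stream
        from ``(seed, salt)`` so outputs do not depend on call order.
    ref_length:
        Length of the synthetic rRNA reference, nucleotides.
    depth:
        Expected read-end count per position (RMS: combined 5'/3' count per
        internucleotide bond; HPS: total 5'-end events per base before
        propensity weighting).
    propensity_sd:
        Standard deviation of the per-position log cleavage propensity
        (lognormal multiplicative bias; 0 disables the noise).
    n_nm_sites, n_psi_sites:
        Number of planted 2'-O-methylation (Nm) and pseudouridine (Psi)
        sites.
    fraction_range:
        Closed interval in [0, 1] from which true modified fractions are
        drawn uniformly.
    u_rate, bg_rate:
        Relative hydrazine cleavage propensities of unmodified uridine
        versus A/C/G background (HPS only); requires u_rate > bg_rate > 0.
    read_length_range:
        Inclusive fragment-length bounds in nucleotides. The default
        (20, 39) keeps every simulated read under the 40-nt read-selection
        cutoff of the RMS protocol, so the filter is a pass-through on
        synthetic data while still being exercised.
    min_spacing:
        Minimum distance between planted sites, nucleotides; 5 guarantees
        that no +/-2 scoring window straddles two sites.
    hps_offset:
        Offset from the cleaved uridine to the counted 5'-end position;
        shared by the generator and the scorer.
    n_proteins, n_kke_proteins, kke_doublets:
        Synthetic proteome size, number of proteins carrying a planted
        lysine-doublet (KKE/D-like) IDR, and doublet count per planted
        segment.
    """

    seed: int = 0
    ref_length: int = 6000
    depth: float = 300.0
    propensity_sd: float = 0.5
    n_nm_sites: int = 55
    n_psi_sites: int = 47
    fraction_range: Tuple[float, float] = (0.5, 1.0)
    u_rate: float = 10.0
    bg_rate: float = 1.0
    read_length_range: Tuple[int, int] = (20, 39)
    min_spacing: int = 5
    hps_offset: int = 0
    n_proteins: int = 40
    n_kke_proteins: int = 5
    kke_doublets: int = 9

    def __post_init__(self) -> None:
        lo, hi = self.fraction_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError(f"fraction_range must satisfy 0 <= lo <= hi <= 1, got {self.fraction_range}")
        if not (self.u_rate > self.bg_rate > 0):
            raise ValueError(f"need u_rate > bg_rate > 0, got u_rate={self.u_rate}, bg_rate={self.bg_rate}")
        rmin, rmax = self.read_length_range
        if not (0 < rmin <= rmax):
            raise ValueError(f"invalid read_length_range {self.read_length_range}")
        if self.ref_length < 50:
            raise ValueError(f"ref_length must be >= 50, got {self.ref_length}")
        if self.min_spacing < 1:
            raise ValueError("min_spacing must be >= 1")
        if self.depth <= 0:
            raise ValueError("depth must be positive")

    def rng(self, salt: int) -> np.random.Generator:
        """Independent random stream for one generator stage."""
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), int(salt)]))

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        """Echo the fully resolved configuration (reproducibility record)."""
        with open(path, "w") as fh:
            yaml.safe_dump({"simulation": self.to_dict()}, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        params = data.get("simulation", data)
        for key in ("fraction_range", "read_length_range"):
            if key in params and isinstance(params[key], list):
                params[key] = tuple(params[key])
        return cls(**params)
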