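"""Parameterization of the generalized telegraph model (GTM).

A gene alternates between OFF and ON states with arbitrary dwell-time
distributions; transcription fires at constant rate r_syn while ON and
each transcript degrades independently at rate r_deg.  The classical
telegraph model is recovered when both dwell times are exponential.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .dwell import DwellModel, make_exponential, make_gamma


@dataclass(frozen=True)
class GTMParameters:
    """Full parameter set of the generalized telegraph model.

    ``off_model``/``on_model`` are the OFF/ON dwell-time distributions;
    ``r_syn`` is the transcription rate while ON (transcripts per unit
    time) and ``r_deg`` the per-molecule degradation rate.  Time is
    conventionally measured in mRNA lifetimes (r_deg = 1), matching how
    snapshot data constrain the model only up to the degradation
    timescale.
    """

    off_model: DwellModel
    on_model: DwellModel
    r_syn: float
    r_deg: float = 1.0

    def __post_init__(self) -> None:
        if self.r_syn < 0:
            raise ValueError(f"r_syn must be >= 0, got {self.r_syn}")
        if not (self.r_deg > 0):
            raise ValueError(f"r_deg must be > 0, got {self.r_deg}")

    @property
    def mean_off(self) -> float:
        return self.off_model.mean()

    @property
    def mean_on(self) -> float:
        return self.on_model.mean()

    def mean_cycle_time(self) -> float:
        """Mean OFF + ON cycle duration."""
        return self.mean_off + self.mean_on

    def burst_frequency(self) -> float:
        """BF = 1 / (<tau_off> + <tau_on>), bursts per unit time."""
        return 1.0 / self.mean_cycle_time()

    def burst_size(self) -> float:
        """BS = r_syn * <tau_on>, mean transcripts made per ON period."""
        return self.r_syn * self.mean_on

    @classmethod
    def from_gamma(
        cls,
        k_off: float,
        r_off: float,
        k_on: float,
        r_on: float,
        r_syn: float,
        r_deg: float = 1.0,
    ) -> "GTMParameters":
        """Gamma-dwell GTM from the five-parameter kinetic vector
        (k_off, r_off, k_on, r_on, r_syn)."""
        return cls(
            off_model=make_gamma(k_off, r_off),
            on_model=make_gamma(k_on, r_on),
            r_syn=float(r_syn),
            r_deg=float(r_deg),
        )

    @classmethod
    def from_exponential(
        cls, r_off: float, r_on: float, r_syn: float, r_deg: float = 1.0
    ) -> "GTMParameters":
        """Classical-telegraph limit: exponential dwells with mean
        activation rate r_off = 1/<tau_off> and inactivation rate
        r_on = 1/<tau_on>."""
        return cls(
            off_model=make_exponential(r_off),
            on_model=make_exponential(r_on),
            r_syn=float(r_syn),
            r_deg=float(r_deg),
        )

    def to_dict(self) -> dict:
        return {
            "off": self.off_model.to_dict(),
            "on": self.on_model.to_dict(),
            "r_syn": self.r_syn,
            "r_deg": self.r_deg,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GTMParameters":
        # YAML 1.1 reads bare off:/on: keys as booleans; accept both
        norm = {
            ("off" if k is False else "on" if k is True else k): v
            for k, v in d.items()
        }
        return cls(
            off_model=DwellModel.from_dict(norm["off"]),
            on_model=DwellModel.from_dict(norm["on"]),
            r_syn=float(norm["r_syn"]),
            r_deg=float(norm.get("r_deg", 1.0)),
        )
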