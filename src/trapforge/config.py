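"""Simulation configuration for synthetic mini-ensemble trap records."""
from __future__ import annotations

from dataclasses import dataclass, asdict, fields

import yaml

from .constants import DEFAULT_TEMPERATURE_K, thermal_energy


@dataclass
class SimConfig:
    """Full kinetic/mechanical parameterization of the synthetic-trace generator.

    Mechanics: a bead in a harmonic trap (``k_trap``, pN/nm) with Brownian
    noise (overdamped, drag ``gamma`` pN*s/nm).  Each attached myosin head
    contributes a ``step_nm`` powerstroke and acts as a spring ``k_head``
    in parallel with the other attached heads and in series with the trap,
    so with N heads attached and cumulative steps S the quasi-static mean
    bead position is ``S * N*k_head / (k_trap + N*k_head)`` and the
    effective stiffness governing the residual Brownian motion is
    ``k_trap + N*k_head``.

    Kinetics: detached heads attach at ``k_attach`` each; attached heads
    detach through two load-dependent (Bell) pathways, an ADP-release
    limited one slowed by resistive load (``k_adp0``, ``d_adp``) and a
    Pi-rebinding one accelerated by load (``pi_mM * k_pi0_per_mM``,
    ``d_pi``).  ``load_sharing`` selects the resistive load entering each
    head's hazard: "total" applies the full ensemble force F = k_trap*mean
    to every attached head (all attached heads experience the resistive
    load); "equal" divides it, F/N.
    """

    k_trap: float                      # trap stiffness, pN/nm
    duration_s: float                  # record length, s
    seed: int                          # RNG seed (mandatory, recorded in outputs)
    n_heads: int = 4                   # motors available to the filament
    step_nm: float = 7.0               # powerstroke size, nm
    k_head: float = 0.6                # per-attached-head stiffness, pN/nm
    gamma: float = 1.9e-5              # bead drag, pN*s/nm (~1 um bead in water)
    temperature_K: float = DEFAULT_TEMPERATURE_K
    sample_rate_hz: float = 5000.0
    k_init: float = 2.0                # event-initiation rate (first head binds), 1/s
    k_attach: float = 40.0             # in-event per-available-head attachment rate, 1/s
    d_attach: float = 1.5              # attachment load distance, nm (stall; load slows binding)
    k_recover: float = 1.0             # refractory->available recovery rate after detachment, 1/s
    k_adp0: float = 16.8               # unloaded ADP-release-limited detachment, 1/s
    d_adp: float = 0.9                 # ADP-release load distance, nm (positive slows)
    pi_mM: float = 0.0                 # phosphate concentration, mM
    k_pi0_per_mM: float = 2.5 / 30.0   # unloaded Pi-induced detachment per mM, 1/(s*mM)
    d_pi: float = 4.1                  # Pi-pathway load distance, nm (positive accelerates)
    load_sharing: str = "total"        # "total" or "equal"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.k_trap <= 0:
            raise ValueError("k_trap must be positive")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.n_heads < 0:
            raise ValueError("n_heads must be >= 0")
        if self.step_nm < 0 or self.k_head < 0:
            raise ValueError("step_nm and k_head must be >= 0")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.temperature_K <= 0:
            raise ValueError("temperature_K must be positive")
        for name in ("k_init", "k_attach", "d_attach", "k_recover", "k_adp0",
                     "pi_mM", "k_pi0_per_mM"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.load_sharing not in ("total", "equal"):
            raise ValueError("load_sharing must be 'total' or 'equal'")
        if not isinstance(self.seed, (int,)) or isinstance(self.seed, bool):
            raise ValueError("seed must be an integer")

    @property
    def kT(self) -> float:
        """Thermal energy, pN*nm."""
        return thermal_energy(self.temperature_K)

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate_hz

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.sample_rate_hz))

    def replace(self, **kwargs) -> "SimConfig":
        d = asdict(self)
        d.update(kwargs)
        return SimConfig(**d)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown SimConfig keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
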