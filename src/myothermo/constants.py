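"""Physical constants of the two-state crossbridge model.

The sliding-filament formalism needs a handful of molecular constants:
the myosin working-stroke size ``h``, the spacing ``l`` between successive
actin sites available to a myosin head, the free energy ``e`` liberated by
hydrolysis of one ATP, and the fraction ``w/e`` of that energy available
as mechanical work of a single crossbridge.  The classical parameter
choice (h = 10 nm, l = 28.6 nm, e = 1e-19 J, w/e = 0.75) satisfies the
model's l >> h requirement and puts the maximum unitary force w/l at
about 2.62 pN.

Muscle-level velocities are measured in muscle lengths per second (Lo/s)
and enter the molecular equations as filament sliding speeds in nm/s per
half-sarcomere; ``half_sarcomere_um`` sets that conversion.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InvalidInputError

AVOGADRO = 6.02214076e23


@dataclass(frozen=True)
class CrossbridgeConstants:
    """Constants of the two-state crossbridge cycle.

    Parameters
    ----------
    h
        Myosin step size (actin translocation per ATP split), nm.
    l
        Distance between successive actin sites a myosin head can
        reach, nm.  The model requires ``l >> h``.
    e
        Free energy per ATP molecule, J.
    w_over_e
        Fraction of ``e`` available as maximum mechanical work of one
        crossbridge (dimensionless).
    half_sarcomere_um
        Half-sarcomere length used to convert muscle shortening in
        Lo/s into filament sliding in nm/s, µm.
    temperature_K
        Bath temperature, K (29 °C experiments → 302.15 K).
    avogadro
        Avogadro's number, mol⁻¹.
    """

    h: float = 10.0
    l: float = 28.6
    e: float = 1e-19
    w_over_e: float = 0.75
    half_sarcomere_um: float = 1.0
    temperature_K: float = 302.15
    avogadro: float = AVOGADRO

    def __post_init__(self) -> None:
        for name in ("h", "l", "e", "w_over_e", "half_sarcomere_um",
                     "temperature_K", "avogadro"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be positive")
        if self.l / self.h < 2:
            raise InvalidInputError(
                f"actin site spacing l={self.l} nm must be well above the "
                f"step size h={self.h} nm (l/h >= 2)")

    @property
    def w(self) -> float:
        """Maximum mechanical work of one crossbridge, J."""
        return self.w_over_e * self.e

    @property
    def w_over_l_pN(self) -> float:
        """Upper bound on the unitary crossbridge force w/l, pN."""
        # w [J] / l [nm] = w/l * 1e9 N -> * 1e12 pN/N
        return self.w / (self.l * 1e-9) * 1e12

    def lo_per_s_to_nm_per_s(self, v_lo_s: float) -> float:
        """Convert a muscle velocity in Lo/s to filament sliding in nm/s
        per half-sarcomere."""
        return v_lo_s * self.half_sarcomere_um * 1e3


DEFAULT_CONSTANTS = CrossbridgeConstants()
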