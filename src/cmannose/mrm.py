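"""MRM transition enumeration and retention-time scheduling.

For targeted detection of (glyco)peptides on a triple-quadrupole instrument,
all precursor ions of charge 2-4 are crossed with all singly-protonated b/y
product ions and filtered to the instrument's m/z range (250-1250 by
default).  Scheduled methods place each transition in a detection window
(default 300 s wide, 1.8 s target scan time) centred on its expected
retention time; transitions without a known RT go to an unscheduled block.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional, Sequence

from .glyco import PROTON, GlycoSpecies, fragment_ions

#: Linear collision-energy seeds CE = a * precursor_mz + b per precursor
#: charge, in the range typical for QTrap-class instruments.  These are
#: starting points only — CEs are expected to be optimised per transition
#: and can be overridden exactly via ``ce_overrides``.
CE_DEFAULTS: dict[int, tuple[float, float]] = {
    2: (0.050, 5.0),
    3: (0.040, 4.0),
    4: (0.035, 3.0),
}


@dataclass(frozen=True)
class Transition:
    """One precursor → product MRM transition."""

    peptide: str
    species_label: str
    precursor_mz: float
    precursor_charge: int
    product_mz: float
    product_label: str
    collision_energy: Optional[float] = None
    expected_rt: Optional[float] = None


@dataclass(frozen=True)
class ScheduleWindow:
    """An acquisition window around the expected elution time."""

    center_rt: float            # minutes
    width: float = 300.0        # seconds
    target_scan_time: float = 1.8  # seconds

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("window width must be positive")

    @property
    def start_rt(self) -> float:
        return self.center_rt - self.width / 120.0

    @property
    def end_rt(self) -> float:
        return self.center_rt + self.width / 120.0


def default_collision_energy(precursor_mz: float, charge: int) -> float:
    """Linear-in-m/z collision-energy seed for a given precursor charge.

    Defaults are monotone: at fixed m/z a higher charge never yields a larger
    CE.  Charges above 4 fall back to the 4+ parameters.
    """
    if charge < 2:
        raise ValueError("collision-energy seeds are defined for charge >= 2")
    slope, intercept = CE_DEFAULTS[min(charge, 4)]
    return slope * precursor_mz + intercept


def enumerate_transitions(
    species: Sequence[GlycoSpecies],
    mz_min: float = 250.0,
    mz_max: float = 1250.0,
    charges: Sequence[int] = (2, 3, 4),
    include_glycan_products: bool = False,
    glycan_sites: Sequence[int] = (),
    ce_overrides: Optional[Mapping[tuple[str, str, int, str], float]] = None,
) -> list[Transition]:
    """All precursor × b/y product transitions inside the m/z window.

    Product ions are singly protonated.  With ``include_glycan_products`` the
    hexoses of a species are placed on the first ``n_hex`` positions of
    ``glycan_sites`` (1-based peptide coordinates) so that product ions carry
    their glycans; otherwise products are computed from the bare peptide.
    ``ce_overrides`` maps ``(peptide, species_label, precursor_charge,
    product_label)`` to an exact collision energy, replacing the linear seed.
    Ordering is deterministic: species order, then charge, then b before y by
    index.  An empty result is allowed.
    """
    out: list[Transition] = []
    for sp in species:
        if include_glycan_products and sp.n_hex > 0:
            if len(glycan_sites) < sp.n_hex:
                raise ValueError(
                    f"species {sp.label} carries {sp.n_hex} hexoses but only "
                    f"{len(glycan_sites)} glycan sites were given"
                )
            site_mods = {pos: "Hex" for pos in glycan_sites[: sp.n_hex]}
        else:
            site_mods = None
        products = fragment_ions(sp.peptide, site_mods=site_mods)
        for z in charges:
            prec_mz = (sp.neutral_mass + z * PROTON) / z
            if not (mz_min <= prec_mz <= mz_max):
                continue
            for label, prod_mz in products:
                if not (mz_min <= prod_mz <= mz_max):
                    continue
                key = (sp.peptide.sequence, sp.label, z, label)
                ce = (
                    ce_overrides[key]
                    if ce_overrides and key in ce_overrides
                    else default_collision_energy(prec_mz, z)
                )
                out.append(
                    Transition(
                        peptide=sp.peptide.sequence,
                        species_label=sp.label,
                        precursor_mz=prec_mz,
                        precursor_charge=z,
                        product_mz=prod_mz,
                        product_label=label,
                        collision_energy=ce,
                    )
                )
    return out


def schedule(
    transitions: Iterable[Transition],
    rt_map: Mapping[str, float],
    width: float = 300.0,
    target_scan_time: float = 1.8,
) -> list[tuple[Transition, Optional[ScheduleWindow]]]:
    """Assign each transition a detection window centred on its expected RT.

    ``rt_map`` maps peptide sequences to expected RTs in minutes.  Transitions
    whose peptide has no RT are returned with ``None`` (the unscheduled block).
    """
    scheduled: list[tuple[Transition, Optional[ScheduleWindow]]] = []
    for t in transitions:
        rt = rt_map.get(t.peptide)
        if rt is None:
            scheduled.append((t, None))
        else:
            scheduled.append(
                (
                    replace(t, expected_rt=rt),
                    ScheduleWindow(rt, width, target_scan_time),
                )
            )
    return scheduled
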