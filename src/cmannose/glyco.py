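"""Glycopeptide masses, glycoform ladders, fragment ions and EICs.

A C-mannose adds one hexose (monoisotopic 162.05282 Da) to a tryptophan and
survives ionisation and fragmentation, so glycoforms of one peptide appear as
a mass ladder spaced by the hexose delta.  TSR peptides may additionally
carry an O-fucose (dHex, 146.05791 Da) on Ser/Thr, optionally extended by a
glucose (another hexose) to the Fuc-Glc disaccharide.  This module computes
neutral masses and m/z for such species, enumerates the full glycoform
ladder, generates singly-protonated b/y fragment ions (glycans treated as
non-labile), and extracts/quantifies ion chromatograms from centroided MS1
runs at an absolute mass tolerance (default 0.3 Da).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
from pyteomics import mass as _ptmass

# Monoisotopic constants (Da)
WATER = 18.010565
PROTON = 1.007276
HEX = 162.05282          #: hexose (C-mannose / glucose) residue delta
DEOXYHEX = 146.05791     #: deoxyhexose (O-fucose) residue delta
CARBAMIDOMETHYL = 57.02146

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
#: residue monoisotopic masses, restricted to the 20 standard amino acids
RESIDUE_MASS: dict[str, float] = {aa: _ptmass.std_aa_mass[aa] for aa in STANDARD_AA}

FUCOSYL_STATES = ("none", "Fuc", "FucGlc")
FUCOSYL_DELTA = {"none": 0.0, "Fuc": DEOXYHEX, "FucGlc": DEOXYHEX + HEX}

#: named glycan deltas accepted wherever a site modification is specified
GLYCAN_MASS = {"Hex": HEX, "Fuc": DEOXYHEX, "FucGlc": DEOXYHEX + HEX}


@dataclass(frozen=True)
class Peptide:
    """A peptide with fixed modifications and glycosylation capacity.

    ``fixed_mods`` maps residue letters to per-residue mass deltas
    (carbamidomethyl on C by default).  ``n_consensus_trp`` is the number of
    C-mannosylatable tryptophans and is caller-specified: whether a W is in
    consensus can depend on sequence beyond the peptide's boundaries.
    """

    sequence: str
    fixed_mods: tuple[tuple[str, float], ...] = (("C", CARBAMIDOMETHYL),)
    n_consensus_trp: int = 0
    has_ofucose_site: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("peptide sequence must be non-empty")
        object.__setattr__(self, "sequence", self.sequence.upper())
        if isinstance(self.fixed_mods, Mapping):
            object.__setattr__(
                self, "fixed_mods", tuple(sorted(self.fixed_mods.items()))
            )
        else:
            object.__setattr__(self, "fixed_mods", tuple(self.fixed_mods))
        if self.n_consensus_trp < 0:
            raise ValueError("n_consensus_trp must be >= 0")
        if self.n_consensus_trp > self.sequence.count("W"):
            raise ValueError(
                f"n_consensus_trp={self.n_consensus_trp} exceeds tryptophan count "
                f"({self.sequence.count('W')}) in {self.sequence!r}"
            )

    @property
    def mod_map(self) -> dict[str, float]:
        return dict(self.fixed_mods)


def _residue_masses(p: Peptide) -> np.ndarray:
    mods = p.mod_map
    out = np.empty(len(p.sequence))
    for i, aa in enumerate(p.sequence):
        try:
            out[i] = RESIDUE_MASS[aa]
        except KeyError:
            raise ValueError(
                f"unknown residue {aa!r} at position {i + 1} of {p.sequence!r}"
            ) from None
        out[i] += mods.get(aa, 0.0)
    return out


def peptide_neutral_mass(p: Peptide) -> float:
    """Neutral monoisotopic mass: residue masses + water + fixed-mod deltas."""
    return float(_residue_masses(p).sum() + WATER)


def glyco_mass(p: Peptide, n_hex: int, fucosyl_state: str = "none") -> float:
    """Neutral mass of a glycoform: peptide + n_hex hexoses + fucosyl delta."""
    if n_hex < 0 or n_hex > p.n_consensus_trp:
        raise ValueError(
            f"n_hex={n_hex} outside [0, n_consensus_trp={p.n_consensus_trp}]"
        )
    if fucosyl_state not in FUCOSYL_DELTA:
        raise ValueError(f"fucosyl_state must be one of {FUCOSYL_STATES}")
    if fucosyl_state != "none" and not p.has_ofucose_site:
        raise ValueError("fucosyl_state set on a peptide without an O-fucose site")
    return peptide_neutral_mass(p) + n_hex * HEX + FUCOSYL_DELTA[fucosyl_state]


@dataclass(frozen=True)
class GlycoSpecies:
    """One glycoform of a peptide at a given charge state."""

    peptide: Peptide
    n_hex: int
    fucosyl_state: str = "none"
    charge: int = 2

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError("charge must be >= 1")
        # delegates the remaining invariant checks
        glyco_mass(self.peptide, self.n_hex, self.fucosyl_state)

    @property
    def neutral_mass(self) -> float:
        return glyco_mass(self.peptide, self.n_hex, self.fucosyl_state)

    @property
    def mz(self) -> float:
        return (self.neutral_mass + self.charge * PROTON) / self.charge

    @property
    def label(self) -> str:
        base = f"Hex{self.n_hex}"
        if self.fucosyl_state != "none":
            base += f"+{self.fucosyl_state}"
        return base


def enumerate_glycoforms(p: Peptide, charge: int = 2) -> list[GlycoSpecies]:
    """Full glycoform ladder of ``p``: Hex 0..n_consensus_trp crossed with the
    available fucosyl states, in deterministic order (n_hex ascending, then
    none < Fuc < FucGlc)."""
    fuc_states = FUCOSYL_STATES if p.has_ofucose_site else ("none",)
    return [
        GlycoSpecies(p, n, f, charge)
        for n in range(p.n_consensus_trp + 1)
        for f in fuc_states
    ]


def _site_mod_masses(
    p: Peptide, site_mods: Optional[Mapping[int, Union[str, float]]]
) -> tuple[np.ndarray, list[str]]:
    """Per-position glycan masses (0-filled) and per-position labels."""
    masses = np.zeros(len(p.sequence))
    names = [""] * len(p.sequence)
    if site_mods:
        for pos, glycan in site_mods.items():
            if not 1 <= pos <= len(p.sequence):
                raise ValueError(
                    f"modification position {pos} outside peptide of length "
                    f"{len(p.sequence)}"
                )
            if isinstance(glycan, str):
                if glycan not in GLYCAN_MASS:
                    raise ValueError(f"unknown glycan {glycan!r}")
                masses[pos - 1] += GLYCAN_MASS[glycan]
                names[pos - 1] = glycan
            else:
                masses[pos - 1] += float(glycan)
                names[pos - 1] = f"{float(glycan):.2f}"
    return masses, names


def fragment_ions(
    p: Peptide,
    site_mods: Optional[Mapping[int, Union[str, float]]] = None,
    series: Sequence[str] = ("b", "y"),
    max_index: Optional[int] = None,
) -> list[tuple[str, float]]:
    """Singly protonated b/y fragment ions of ``p``.

    ``site_mods`` maps 1-based residue positions to a glycan name ("Hex",
    "Fuc", "FucGlc") or an explicit mass delta; the glycan mass is carried by
    every fragment containing the modified residue (C-mannose is non-labile).
    ``max_index`` caps the fragment index (default: full ladder, n−1).
    """
    n = len(p.sequence)
    res = _residue_masses(p)
    mod_masses, mod_names = _site_mod_masses(p, site_mods)
    res = res + mod_masses
    top = n - 1 if max_index is None else max_index
    if top > n - 1 or top < 0:
        raise ValueError(f"max_index={max_index} out of range for length {n}")
    for s in series:
        if s not in ("b", "y"):
            raise ValueError(f"unsupported ion series {s!r}")
    prefix = np.concatenate([[0.0], np.cumsum(res)])
    total = prefix[n] + WATER

    def suffix_label(idx_range: range) -> str:
        names = [mod_names[i] for i in idx_range if mod_names[i]]
        return "+" + "+".join(names) if names else ""

    out: list[tuple[str, float]] = []
    if "b" in series:
        for i in range(1, top + 1):
            out.append((f"b{i}" + suffix_label(range(i)), float(prefix[i] + PROTON)))
    if "y" in series:
        for j in range(1, top + 1):
            mz = total - prefix[n - j] + PROTON
            out.append((f"y{j}" + suffix_label(range(n - j, n)), float(mz)))
    return out


@dataclass(frozen=True)
class Scan:
    """One centroided MS1 scan."""

    rt: float
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "mz", np.asarray(self.mz, dtype=float))
        object.__setattr__(self, "intensity", np.asarray(self.intensity, dtype=float))
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must have equal length")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")


@dataclass(frozen=True)
class SpectrumRun:
    """A time-ordered sequence of centroided MS1 scans."""

    scans: tuple[Scan, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "scans", tuple(self.scans))
        rts = [s.rt for s in self.scans]
        if any(b < a for a, b in zip(rts, rts[1:])):
            raise ValueError("scan retention times must be non-decreasing")

    def __len__(self) -> int:
        return len(self.scans)

    def total_ion_current(self) -> np.ndarray:
        return np.array([s.intensity.sum() for s in self.scans])


@dataclass(frozen=True)
class Chromatogram:
    """An extracted ion trace: per-MS1-scan summed intensity near a target m/z."""

    rt: np.ndarray
    intensity: np.ndarray
    target_mz: float
    tol: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "rt", np.asarray(self.rt, dtype=float))
        object.__setattr__(self, "intensity", np.asarray(self.intensity, dtype=float))
        if self.rt.shape != self.intensity.shape:
            raise ValueError("rt and intensity must have equal length")
        if self.rt.size > 1 and np.any(np.diff(self.rt) <= 0):
            raise ValueError("retention times must be strictly increasing")

    @property
    def apex_index(self) -> int:
        return int(np.argmax(self.intensity)) if self.intensity.size else -1

    @property
    def apex_rt(self) -> float:
        return float(self.rt[self.apex_index]) if self.rt.size else float("nan")

    @property
    def apex_intensity(self) -> float:
        return float(self.intensity.max()) if self.intensity.size else 0.0

    def area(self) -> float:
        if self.rt.size < 2:
            return 0.0
        return float(np.trapezoid(self.intensity, self.rt))


def extract_eic(run: SpectrumRun, target_mz: float, tol: float = 0.3) -> Chromatogram:
    """Extract the ion chromatogram of ``target_mz`` ± ``tol`` (absolute Da).

    One point per MS1 scan: the sum of centroid intensities within the
    tolerance window.  An empty run yields an empty chromatogram.
    """
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    rts = np.array([s.rt for s in run.scans])
    intens = np.array(
        [
            float(s.intensity[np.abs(s.mz - target_mz) <= tol].sum())
            for s in run.scans
        ]
    )
    return Chromatogram(rts, intens, target_mz, tol)


@dataclass(frozen=True)
class GlycoformProfile:
    """Relative glycoform intensities, normalised to the most intense species."""

    relative: Mapping[str, float]
    max_intensity: float
    max_label: Optional[str]
    all_zero: bool = False


def quantify_glycoforms(
    run: SpectrumRun,
    species: Sequence[GlycoSpecies],
    tol: float = 0.3,
    use_area: bool = False,
    smooth: bool = False,
    smooth_window: int = 7,
    smooth_order: int = 2,
) -> GlycoformProfile:
    """Quantify each glycoform's EIC and normalise to the maximum.

    The default quantity is the EIC apex (max point); ``use_area`` switches
    to the integrated area.  ``smooth`` applies Savitzky-Golay smoothing to
    each trace before apex picking.  All species must share one peptide.
    """
    if not species:
        raise ValueError("species list must be non-empty")
    peptides = {s.peptide for s in species}
    if len(peptides) > 1:
        raise ValueError("all species must derive from the same peptide")
    values: dict[str, float] = {}
    for sp in species:
        eic = extract_eic(run, sp.mz, tol)
        trace = eic.intensity
        if smooth and trace.size >= smooth_window:
            from scipy.signal import savgol_filter

            trace = np.clip(savgol_filter(trace, smooth_window, smooth_order), 0, None)
        values[sp.label] = float(np.trapezoid(trace, eic.rt)) if use_area else (
            float(trace.max()) if trace.size else 0.0
        )
    max_int = max(values.values()) if values else 0.0
    if max_int <= 0:
        warnings.warn("all glycoform traces are zero; relative values set to 0")
        return GlycoformProfile({k: 0.0 for k in values}, 0.0, None, all_zero=True)
    max_label = max(values, key=values.get)
    rel = {k: v / max_int for k, v in values.items()}
    return GlycoformProfile(rel, max_int, max_label)
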