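"""Synthetic data with known ground truth for every pipeline stage.

Three generators emulate the screen's inputs: a protein database with
planted WxxW/WxxC/TSR motifs, a label-free quantification experiment with
the WT(3) vs two-knockouts-of-two-clones(3+3) layout, planted
secretion-reduction effects and abundance-dependent (MNAR) dropout, and
centroided MS1 runs containing Gaussian elution peaks for glycoform
mixtures.  Every generator is a pure function of its parameters and seed,
and serialises a truth record sufficient to compute the expected output of
each downstream stage without re-simulation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .glyco import GlycoSpecies, Scan, SpectrumRun
from .motif import ProteinRecord
from .secretome import Design, LfqMatrix, default_design

#: background alphabet for simulated sequences: W and C withheld so that the
#: only consensus sites are the planted ones
DEPLETED_ALPHABET = "ADEFGHIKLMNPQRSTVY"
FULL_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SyntheticTruth:
    """Ground truth serialised alongside each generated dataset."""

    seed: int
    params: dict = field(default_factory=dict)
    motif_sites: dict = field(default_factory=dict)   # acc -> [{start, kind, w_positions}]
    effects: dict = field(default_factory=dict)       # acc -> {ko: log2 effect}
    mnar: dict = field(default_factory=dict)
    extracellular: list = field(default_factory=list)
    pfam: dict = field(default_factory=dict)
    decoys: list = field(default_factory=list)
    glycoforms: dict = field(default_factory=dict)    # label -> {mz, ratio, apex_rt}
    overlapping_mz: list = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path, encoding="utf-8") as fh:
            return cls(**json.load(fh))

    def planted_site_positions(self, acc: str) -> list[int]:
        """All consensus-W positions planted in protein ``acc``."""
        out: list[int] = []
        for site in self.motif_sites.get(acc, []):
            out.extend(site["w_positions"])
        return sorted(out)


def _plant(rng: np.random.Generator, kind: str, filler: str) -> tuple[str, list[int]]:
    """Build a motif window; returns (window, 1-based W offsets within it)."""
    x = lambda: filler[rng.integers(len(filler))]
    if kind == "WxxW":
        return "W" + x() + x() + "W", [1]
    if kind == "WxxC":
        return "W" + x() + x() + "C", [1]
    if kind == "TSR":
        return (
            "W" + x() + x() + "W" + x() + x() + "W" + x() + x() + "C",
            [1, 4, 7],
        )
    raise ValueError(f"unknown motif kind {kind!r}")


def simulate_protein_db(
    n_proteins: int = 400,
    motif_fraction: float = 0.3,
    seed: int = 0,
    length_range: tuple[int, int] = (100, 800),
    deplete_w: bool = True,
    tsr_fraction: float = 0.35,
) -> tuple[list[ProteinRecord], SyntheticTruth]:
    """Random protein database with motifs planted at recorded positions.

    With ``deplete_w`` (default) the background alphabet excludes W and C, so
    planted sites are exactly the scannable ones; disabling it allows
    spurious consensus sites.  ``motif_fraction`` of proteins receive 1-3
    planted motifs; ``tsr_fraction`` of those plantings are full
    WxxWxxWxxC motifs, the rest split between lone WxxW and WxxC.
    """
    if not 0 <= motif_fraction <= 1:
        raise ValueError("motif_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    alphabet = DEPLETED_ALPHABET if deplete_w else FULL_ALPHABET
    filler = DEPLETED_ALPHABET  # motif x-positions never create extra sites
    records: list[ProteinRecord] = []
    truth = SyntheticTruth(
        seed=seed,
        params={
            "n_proteins": n_proteins,
            "motif_fraction": motif_fraction,
            "length_range": list(length_range),
            "deplete_w": deplete_w,
            "tsr_fraction": tsr_fraction,
        },
    )
    n_motif = int(round(motif_fraction * n_proteins))
    motif_idx = set(rng.choice(n_proteins, size=n_motif, replace=False).tolist())
    kinds = ["TSR", "WxxW", "WxxC"]
    for i in range(n_proteins):
        acc = f"SYN{i:04d}"
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = list(alphabet[j] for j in rng.integers(len(alphabet), size=length))
        sites = []
        if i in motif_idx:
            n_plant = int(rng.integers(1, 4))
            cursor = int(rng.integers(1, 20))
            for _ in range(n_plant):
                u = rng.random()
                kind = "TSR" if u < tsr_fraction else kinds[1 + int(u * 1e6) % 2]
                window, w_off = _plant(rng, kind, filler)
                if cursor + len(window) > length - 4:
                    break
                seq[cursor : cursor + len(window)] = window
                sites.append(
                    {
                        "start": cursor + 1,
                        "kind": kind,
                        "w_positions": [cursor + o for o in w_off],
                    }
                )
                cursor += len(window) + int(rng.integers(8, 40))
        truth.motif_sites[acc] = sites
        records.append(ProteinRecord(acc, "".join(seq)))
    return records, truth


#: Pfam names used for decoration of simulated proteins (TSP_1 is reserved
#: for proteins carrying a planted TSR motif)
_DOMAIN_POOL = ("EGF", "Kringle", "fn3", "Sushi", "Laminin_G_1", "VWC")


@dataclass
class SyntheticLfqExperiment:
    """A generated quantification experiment with its annotations and truth."""

    matrix: LfqMatrix
    records: list[ProteinRecord]
    gocc: dict[str, frozenset[str]]
    pfam: dict[str, frozenset[str]]
    truth: SyntheticTruth


def simulate_lfq_experiment(
    design: Optional[Design] = None,
    n_proteins: int = 400,
    n_affected: int = 20,
    effect: float = -1.5,
    effect_kos: Sequence[str] = ("DPY19L1", "DPY19L3"),
    mnar_center: float = 22.0,
    mnar_scale: float = 1.0,
    mnar: bool = True,
    seed: int = 0,
    db: Optional[tuple[list[ProteinRecord], SyntheticTruth]] = None,
    base_mean: float = 25.0,
    base_sd: float = 2.0,
    rep_sd: float = 0.5,
    n_decoys: int = 15,
    frac_extracellular: float = 0.85,
    frac_single_peptide: float = 0.05,
    tsp1_bias: float = 0.6,
) -> SyntheticLfqExperiment:
    """Simulate a proteinGroups-style LFQ experiment with planted effects.

    Per protein, a base log2 abundance ~ Normal(base_mean, base_sd²) plus
    replicate noise Normal(0, rep_sd²); affected motif-bearing extracellular
    proteins get ``effect`` added (in log2) in the samples of their assigned
    knockout(s).  Missingness is abundance-dependent: a cell of underlying
    log2 value x is missing with probability logistic((mnar_center − x) /
    mnar_scale).  Contaminant / reverse / only-by-site decoy rows are
    injected.  Missing values are exported as NaN (written as 0 in the
    proteinGroups dialect).
    """
    design = design or default_design()
    for ko in effect_kos:
        if ko not in design.ko:
            raise ValueError(f"effect KO {ko!r} not in the design")
    ss = np.random.SeedSequence(seed)
    db_seed, main_seed = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))
    if db is None:
        db = simulate_protein_db(n_proteins, motif_fraction=0.3, seed=db_seed)
    records, db_truth = db
    if len(records) != n_proteins:
        n_proteins = len(records)
    rng = np.random.default_rng(main_seed)
    accs = [r.id for r in records]

    extracellular = [a for a in accs if rng.random() < frac_extracellular]
    extr = set(extracellular)

    tsr_accs = {
        a
        for a, sites in db_truth.motif_sites.items()
        if any(s["kind"] == "TSR" for s in sites)
    }
    motif_accs = {a for a, sites in db_truth.motif_sites.items() if sites}
    pfam: dict[str, frozenset[str]] = {}
    for a in accs:
        doms: set[str] = set()
        if a in tsr_accs:
            doms.add("TSP_1")
        if rng.random() < 0.4:
            doms.add(_DOMAIN_POOL[int(rng.integers(len(_DOMAIN_POOL)))])
        if doms:
            pfam[a] = frozenset(doms)

    # choose affected proteins among motif-bearing extracellular ones,
    # biased toward TSP_1 carriers so domain enrichment is recoverable
    eligible_tsp = sorted(tsr_accs & extr)
    eligible_other = sorted((motif_accs - tsr_accs) & extr)
    n_tsp = min(int(round(tsp1_bias * n_affected)), len(eligible_tsp))
    n_other = min(n_affected - n_tsp, len(eligible_other))
    affected = [
        eligible_tsp[i]
        for i in rng.choice(len(eligible_tsp), size=n_tsp, replace=False)
    ] + [
        eligible_other[i]
        for i in rng.choice(len(eligible_other), size=n_other, replace=False)
    ]
    if len(affected) < n_affected:
        raise ValueError(
            f"only {len(affected)} motif-bearing extracellular proteins "
            f"available for {n_affected} planted effects"
        )
    effects: dict[str, dict[str, float]] = {}
    for a in affected:
        u = rng.random()
        if len(effect_kos) >= 2 and u < 0.2:
            targets = list(effect_kos)
        else:
            targets = [effect_kos[int(rng.integers(len(effect_kos)))]]
        effects[a] = {ko: effect for ko in targets}

    samples = list(design.all_samples)
    ko_of_sample = {}
    for ko, clones in design.ko.items():
        for reps in clones.values():
            for s in reps:
                ko_of_sample[s] = ko

    base = rng.normal(base_mean, base_sd, size=n_proteins)
    log2_vals = np.empty((n_proteins, len(samples)))
    for j, s in enumerate(samples):
        shift = np.array(
            [effects.get(a, {}).get(ko_of_sample.get(s), 0.0) for a in accs]
        )
        log2_vals[:, j] = base + shift + rng.normal(0.0, rep_sd, size=n_proteins)

    if mnar:
        p_miss = expit((mnar_center - log2_vals) / mnar_scale)
        missing = rng.random(log2_vals.shape) < p_miss
    else:
        missing = np.zeros(log2_vals.shape, dtype=bool)

    intens = np.where(missing, np.nan, np.exp2(log2_vals))
    intensities = pd.DataFrame(intens, index=accs, columns=samples)

    peptides = rng.poisson(8, size=n_proteins) + 2
    single = rng.random(n_proteins) < frac_single_peptide
    single &= ~np.isin(accs, affected)  # planted effects stay recoverable
    peptides = np.where(single, 1, peptides)
    meta = pd.DataFrame(
        {
            "members": [(a,) for a in accs],
            "peptides": peptides,
            "contaminant": False,
            "reverse": False,
            "only_by_site": False,
        },
        index=accs,
    )

    decoy_rows = []
    decoy_ids = []
    flags = ["contaminant", "reverse", "only_by_site"]
    prefix = {"contaminant": "CON__", "reverse": "REV__", "only_by_site": "OBS__"}
    for d in range(n_decoys):
        flag = flags[d % 3]
        did = f"{prefix[flag]}D{d:03d}"
        decoy_ids.append(did)
        row = {
            "members": (did,),
            "peptides": int(rng.integers(1, 12)),
            "contaminant": flag == "contaminant",
            "reverse": flag == "reverse",
            "only_by_site": flag == "only_by_site",
        }
        decoy_rows.append(row)
        vals = np.exp2(rng.normal(base_mean, base_sd, size=len(samples)))
        intensities.loc[did] = vals
    if decoy_rows:
        meta = pd.concat([meta, pd.DataFrame(decoy_rows, index=decoy_ids)])
        intensities = intensities.loc[meta.index]

    matrix = LfqMatrix(intensities, meta, design)
    gocc = {a: frozenset(EXTRACELLULAR_TAG) for a in extracellular}
    truth = SyntheticTruth(
        seed=seed,
        params={
            "n_proteins": n_proteins,
            "n_affected": n_affected,
            "effect": effect,
            "base_mean": base_mean,
            "base_sd": base_sd,
            "rep_sd": rep_sd,
            "n_decoys": n_decoys,
            "frac_extracellular": frac_extracellular,
            "frac_single_peptide": frac_single_peptide,
        },
        motif_sites=db_truth.motif_sites,
        effects=effects,
        mnar={
            "enabled": mnar,
            "center": mnar_center,
            "scale": mnar_scale,
            "realised_fraction": float(missing.mean()),
        },
        extracellular=extracellular,
        pfam={a: sorted(d) for a, d in pfam.items()},
        decoys=decoy_ids,
    )
    return SyntheticLfqExperiment(matrix, records, gocc, pfam, truth)


#: the GO-CC slim term attached to simulated extracellular proteins
EXTRACELLULAR_TAG = ("extracellular region",)


def simulate_ms1_run(
    species: Sequence[GlycoSpecies],
    ratios: Sequence[float],
    apices: Sequence[float],
    peak_width: float = 0.15,
    snr: float = 100.0,
    seed: int = 0,
    cadence_s: float = 3.0,
    rt_span: Optional[tuple[float, float]] = None,
    base_intensity: float = 1.0e6,
    n_noise_peaks: int = 5,
    overlap_tol: float = 0.6,
) -> tuple[SpectrumRun, SyntheticTruth]:
    """MS1 run with one Gaussian elution profile per glycoform species.

    Scans are placed at a fixed cadence; each species contributes a centroid
    at its m/z with intensity ``base_intensity * ratio *
    exp(-(t - apex)^2 / (2 width^2))`` (width in minutes).  A uniform noise
    floor of amplitude ``base_intensity / snr`` is added as random centroids.
    Species whose m/z lie within ``overlap_tol`` of each other are flagged in
    the truth record.
    """
    if len(species) != len(ratios) or len(species) != len(apices):
        raise ValueError("species, ratios and apices must have equal length")
    if any(r < 0 for r in ratios):
        raise ValueError("ratios must be non-negative")
    if peak_width <= 0:
        raise ValueError("peak width must be positive")
    rng = np.random.default_rng(seed)
    if rt_span is None:
        lo = min(apices) - 6 * peak_width if apices else 0.0
        hi = max(apices) + 6 * peak_width if apices else 1.0
        rt_span = (max(0.0, lo), hi)
    times = np.arange(rt_span[0], rt_span[1], cadence_s / 60.0)
    mzs = np.array([sp.mz for sp in species])
    amp = base_intensity * np.asarray(ratios, dtype=float)
    noise_amp = base_intensity / snr
    mz_lo, mz_hi = (mzs.min() - 50, mzs.max() + 50) if len(mzs) else (300.0, 1600.0)

    scans = []
    for t in times:
        profile = amp * np.exp(-((t - np.asarray(apices)) ** 2) / (2 * peak_width**2))
        keep = profile > 0
        scan_mz = list(mzs[keep])
        scan_int = list(profile[keep])
        for _ in range(n_noise_peaks):
            scan_mz.append(float(rng.uniform(mz_lo, mz_hi)))
            scan_int.append(float(rng.uniform(0, noise_amp)))
        order = np.argsort(scan_mz)
        scans.append(
            Scan(float(t), np.asarray(scan_mz)[order], np.asarray(scan_int)[order])
        )
    run = SpectrumRun(tuple(scans))

    overlaps = [
        [species[i].label, species[j].label]
        for i in range(len(species))
        for j in range(i + 1, len(species))
        if abs(mzs[i] - mzs[j]) <= overlap_tol
    ]
    truth = SyntheticTruth(
        seed=seed,
        params={
            "peak_width": peak_width,
            "snr": snr,
            "cadence_s": cadence_s,
            "base_intensity": base_intensity,
            "rt_span": list(rt_span),
        },
        glycoforms={
            sp.label: {"mz": float(sp.mz), "ratio": float(r), "apex_rt": float(a)}
            for sp, r, a in zip(species, ratios, apices)
        },
        overlapping_mz=overlaps,
    )
    return run, truth
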