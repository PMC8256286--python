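"""Readers and writers for the pipeline's file formats.

Dialects: FASTA (plain or UniProt ``sp|ACC|NAME`` headers), MaxQuant
proteinGroups tab-separated tables, Perseus-style annotation TSVs (accession
→ GO-CC slim names and Pfam domains, ";"-separated), a simple JSON format
for centroided MS1 runs (optional mzML through the same contract), and a
transition-list CSV importable by vendor tools.  All tables are
tab-separated UTF-8 with headers; missing values are written as empty cells
(LFQ intensities as 0, the MaxQuant convention).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from Bio import SeqIO

from .glyco import Scan, SpectrumRun
from .motif import ProteinRecord
from .mrm import ScheduleWindow, Transition
from .secretome import Design, ImputeConfig, LfqMatrix

PathLike = Union[str, Path]

ID_COLUMN = "Majority protein IDs"
PEPTIDES_COLUMN = "Peptides"
FLAG_COLUMNS = {
    "contaminant": "Potential contaminant",
    "reverse": "Reverse",
    "only_by_site": "Only identified by site",
}
LFQ_PREFIX = "LFQ intensity "


def _accession_from_header(header: str) -> str:
    """Extract the accession from ``sp|ACC|NAME``-style ids, else the first token."""
    token = header.split()[0]
    parts = token.split("|")
    if len(parts) >= 3 and parts[0] in ("sp", "tr"):
        return parts[1]
    return token


def read_fasta(path: PathLike) -> list[ProteinRecord]:
    """Read protein records; UniProt-style accessions are extracted."""
    records = [
        ProteinRecord(_accession_from_header(rec.id), str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    seen: set[str] = set()
    for r in records:
        if r.id in seen:
            raise ValueError(f"duplicate accession {r.id!r} in {path}")
        seen.add(r.id)
    return records


def write_fasta(records: Iterable[ProteinRecord], path: PathLike, width: int = 60) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_protein_groups(path: PathLike, design: Design) -> LfqMatrix:
    """Read a MaxQuant proteinGroups table into an :class:`LfqMatrix`.

    Required columns: the semicolon-separated ID column, the peptide count,
    the "+"-flagged decoy columns, and one ``LFQ intensity <sample>`` column
    per design sample.  Zero intensities become missing (NaN).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = [ID_COLUMN, PEPTIDES_COLUMN, *FLAG_COLUMNS.values()] + [
        LFQ_PREFIX + s for s in design.all_samples
    ]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    ids = df[ID_COLUMN].astype(str)
    meta = pd.DataFrame(
        {
            "members": [tuple(x.split(";")) for x in ids],
            "peptides": pd.to_numeric(df[PEPTIDES_COLUMN]).astype(int).to_numpy(),
            **{
                key: (df[col].fillna("") == "+").to_numpy()
                for key, col in FLAG_COLUMNS.items()
            },
        },
        index=pd.Index(ids, name="group_id"),
    )
    intens = pd.DataFrame(index=meta.index)
    for s in design.all_samples:
        vals = pd.to_numeric(df[LFQ_PREFIX + s]).astype(float).to_numpy()
        intens[s] = np.where(vals > 0, vals, np.nan)
    return LfqMatrix(intens, meta, design)


def write_protein_groups(matrix: LfqMatrix, path: PathLike) -> None:
    """Write an :class:`LfqMatrix` back to the proteinGroups dialect."""
    out = pd.DataFrame(
        {
            ID_COLUMN: [";".join(m) for m in matrix.meta["members"]],
            PEPTIDES_COLUMN: matrix.meta["peptides"].to_numpy(),
        }
    )
    for key, col in FLAG_COLUMNS.items():
        out[col] = np.where(matrix.meta[key].to_numpy(), "+", "")
    for s in matrix.design.all_samples:
        out[LFQ_PREFIX + s] = matrix.intensities[s].fillna(0.0).to_numpy()
    out.to_csv(path, sep="\t", index=False)


ANNOT_ACC = "Accession"
ANNOT_GOCC = "GOCC slim name"
ANNOT_PFAM = "Pfam"


def read_annotation(
    path: PathLike,
) -> tuple[dict[str, frozenset[str]], dict[str, frozenset[str]]]:
    """Read a Perseus-style annotation TSV → (GO-CC slim map, Pfam map)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in (ANNOT_ACC, ANNOT_GOCC, ANNOT_PFAM) if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    gocc: dict[str, frozenset[str]] = {}
    pfam: dict[str, frozenset[str]] = {}
    for _, row in df.iterrows():
        acc = row[ANNOT_ACC]
        terms = frozenset(t for t in row[ANNOT_GOCC].split(";") if t)
        doms = frozenset(d for d in row[ANNOT_PFAM].split(";") if d)
        if terms:
            gocc[acc] = terms
        if doms:
            pfam[acc] = doms
    return gocc, pfam


def write_annotation(
    gocc: Mapping[str, Iterable[str]],
    pfam: Mapping[str, Iterable[str]],
    path: PathLike,
) -> None:
    accs = sorted(set(gocc) | set(pfam))
    df = pd.DataFrame(
        {
            ANNOT_ACC: accs,
            ANNOT_GOCC: [";".join(sorted(gocc.get(a, ()))) for a in accs],
            ANNOT_PFAM: [";".join(sorted(pfam.get(a, ()))) for a in accs],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_run(run: SpectrumRun, path: PathLike) -> None:
    """Write an MS1 run as JSON: a list of (rt_min, [mz], [intensity]) scans."""
    payload = {
        "scans": [
            {
                "rt_min": s.rt,
                "mz": [round(float(v), 6) for v in s.mz],
                "intensity": [round(float(v), 4) for v in s.intensity],
            }
            for s in run.scans
        ]
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh)


def read_run(path: PathLike) -> SpectrumRun:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    return SpectrumRun(
        tuple(
            Scan(s["rt_min"], np.asarray(s["mz"]), np.asarray(s["intensity"]))
            for s in payload["scans"]
        )
    )


def read_mzml(path: PathLike) -> SpectrumRun:
    """Read MS1 spectra from an mzML file into the same run contract."""
    from pyteomics import mzml

    scans = []
    with mzml.MzML(str(path)) as reader:
        for spec in reader:
            if spec.get("ms level") != 1:
                continue
            rt = spec["scanList"]["scan"][0]["scan start time"]
            scans.append(
                Scan(float(rt), np.asarray(spec["m/z array"]), np.asarray(spec["intensity array"]))
            )
    return SpectrumRun(tuple(scans))


TRANSITION_COLUMNS = [
    "peptide",
    "species",
    "precursor_mz",
    "precursor_charge",
    "product_mz",
    "product_label",
    "collision_energy",
    "rt_center_min",
    "window_s",
    "target_scan_time_s",
]


def write_transition_list(
    scheduled: Sequence[tuple[Transition, Optional[ScheduleWindow]]],
    path: PathLike,
) -> None:
    """Write scheduled transitions as a vendor-importable CSV."""
    rows = []
    for t, w in scheduled:
        rows.append(
            {
                "peptide": t.peptide,
                "species": t.species_label,
                "precursor_mz": round(t.precursor_mz, 4),
                "precursor_charge": t.precursor_charge,
                "product_mz": round(t.product_mz, 4),
                "product_label": t.product_label,
                "collision_energy": (
                    round(t.collision_energy, 2) if t.collision_energy is not None else ""
                ),
                "rt_center_min": w.center_rt if w else "",
                "window_s": w.width if w else "",
                "target_scan_time_s": w.target_scan_time if w else "",
            }
        )
    pd.DataFrame(rows, columns=TRANSITION_COLUMNS).to_csv(path, index=False)


@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    """Paths, design and thresholds for an end-to-end screen run."""

    protein_groups: str
    annotation: str
    fasta: Optional[str] = None
    design: Optional[Design] = None
    alpha: float = 0.05
    min_peptides: int = 2
    impute: ImputeConfig = ImputeConfig()
    eic_tol: float = 0.3
    mz_range: tuple[float, float] = (250.0, 1250.0)
    charges: tuple[int, ...] = (2, 3, 4)
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.design is not None:
            d["design"] = {
                "wt": list(self.design.wt),
                "ko": {
                    ko: {c: list(r) for c, r in clones.items()}
                    for ko, clones in self.design.ko.items()
                },
            }
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_file(cls, path: PathLike) -> "PipelineConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        design = None
        if "design" in raw:
            d = raw.pop("design")
            design = Design(
                wt=tuple(d["wt"]),
                ko={
                    ko: {c: tuple(r) for c, r in clones.items()}
                    for ko, clones in d["ko"].items()
                },
            )
        impute = ImputeConfig(**raw.pop("impute", {}))
        if "mz_range" in raw:
            raw["mz_range"] = tuple(raw["mz_range"])
        if "charges" in raw:
            raw["charges"] = tuple(raw["charges"])
        return cls(design=design, impute=impute, **raw)
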