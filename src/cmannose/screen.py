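"""The end-to-end differential secretome screen as a model/results pair.

:class:`SecretomeScreen` holds the data (quantification matrix, GO-CC and
Pfam annotation, optional protein sequences) and the analysis parameters;
``fit(seed)`` executes filter → impute → test → motif-annotate →
candidate-select → enrich → rescreen and returns a :class:`ScreenResults`
carrying the estimates, the per-stage filter report and a ``summary()``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from . import io as cio
from .enrichment import (
    CandidateSelection,
    EnrichmentResult,
    fisher_domain_enrichment,
    rescreen_domain,
    select_candidates,
)
from .motif import GroupMotifAnnotation, ProteinRecord, annotate_groups, motif_positive_groups
from .secretome import (
    DifferentialResult,
    Design,
    FilterReport,
    ImputeConfig,
    LfqMatrix,
    differential_test,
    filter_secretome,
    log2_and_impute,
    per_clone_fold_changes,
)


class PipelineError(RuntimeError):
    """A pipeline stage failure, labelled with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class ScreenResults:
    """Fitted screen: estimates, diagnostics and provenance."""

    filter_report: FilterReport
    log2_matrix: pd.DataFrame
    differential: Mapping[str, DifferentialResult]
    clone_fold_changes: pd.DataFrame
    motif_annotations: Optional[list[GroupMotifAnnotation]]
    candidates: Optional[CandidateSelection]
    enrichment: Optional[list[EnrichmentResult]]
    rescreen: Optional[list[str]]
    alpha: float
    seed: int
    config_hash: str = ""

    def results_table(self) -> pd.DataFrame:
        """Per-group statistics across contrasts, volcano-ready."""
        out = pd.DataFrame(index=self.log2_matrix.index)
        for ko, res in self.differential.items():
            out[f"{ko}_log2_fc"] = res.table["log2_fc"]
            out[f"{ko}_t"] = res.table["t"]
            out[f"{ko}_p"] = res.table["p"]
            out[f"{ko}_significant"] = res.table["significant"]
        if self.motif_annotations is not None:
            call = {a.group_id: a.has_consensus for a in self.motif_annotations}
            out["has_consensus"] = [call.get(g) for g in out.index]
        if self.candidates is not None:
            out["candidate"] = [g in self.candidates.union for g in out.index]
        return out

    def summary(self) -> str:
        rep = self.filter_report
        lines = [
            "Differential secretome screen",
            "=" * 34,
            f"protein groups (initial):        {rep.initial}",
            f"after decoy removal:             {rep.after_decoy_removal}",
            f"extracellular (GO-CC slim):      {rep.after_extracellular}",
            f"identification + detection:      {rep.final}",
            f"detected in all cell lines:      {rep.detected_in_all_lines}",
            "",
        ]
        for ko, res in self.differential.items():
            n_sig = int(res.table["significant"].sum())
            lines.append(f"{ko} vs WT: {n_sig} significant at p <= {self.alpha}")
        if self.candidates is not None:
            for ko, ids in self.candidates.per_ko.items():
                lines.append(f"{ko} motif-bearing candidates: {len(ids)}")
            lines.append(f"union candidates: {len(self.candidates.union)}")
        if self.enrichment:
            lines.append("")
            lines.append("domain enrichment (top 5):")
            for r in self.enrichment[:5]:
                lines.append(
                    f"  {r.domain:<14s} k={r.k}/{r.n} K={r.K}/{r.N} "
                    f"OR={r.odds_ratio:.2f} p={r.p:.3g}"
                )
        if self.rescreen is not None:
            lines.append(f"TSP_1 rescreen of background: {len(self.rescreen)} proteins")
        lines.append("")
        lines.append(f"seed={self.seed} config={self.config_hash or 'n/a'}")
        return "\n".join(lines)


class SecretomeScreen:
    """Differential secretome screen model.

    Parameters
    ----------
    matrix
        The quantification matrix with its design.
    go_annotation
        Accession → GO-CC slim term sets (extracellular filter).
    sequences
        Protein records for motif annotation; without them candidate
        selection and enrichment are skipped.
    domain_annotation
        Accession → Pfam domain sets for enrichment and the rescreen.
    """

    def __init__(
        self,
        matrix: LfqMatrix,
        go_annotation: Mapping[str, frozenset[str]],
        sequences: Optional[Sequence[ProteinRecord]] = None,
        domain_annotation: Optional[Mapping[str, frozenset[str]]] = None,
        min_peptides: int = 2,
        alpha: float = 0.05,
        impute: ImputeConfig = ImputeConfig(),
        rescreen_domain_name: str = "TSP_1",
    ):
        self.matrix = matrix
        self.go_annotation = go_annotation
        self.sequences = list(sequences) if sequences is not None else None
        self.domain_annotation = domain_annotation
        self.min_peptides = min_peptides
        self.alpha = alpha
        self.impute = impute
        self.rescreen_domain_name = rescreen_domain_name

    @classmethod
    def from_files(
        cls,
        protein_groups: str,
        annotation: str,
        design: Optional[Design] = None,
        fasta: Optional[str] = None,
        **kwargs,
    ) -> "SecretomeScreen":
        from .secretome import default_design

        design = design or default_design()
        matrix = cio.read_protein_groups(protein_groups, design)
        gocc, pfam = cio.read_annotation(annotation)
        sequences = cio.read_fasta(fasta) if fasta else None
        return cls(matrix, gocc, sequences=sequences, domain_annotation=pfam, **kwargs)

    def fit(self, seed: Optional[int] = None, config_hash: str = "") -> ScreenResults:
        """Run the full analysis chain; ``seed`` drives the imputation."""
        seed = self.impute.seed if seed is None else seed
        design = self.matrix.design

        try:
            filtered, report = filter_secretome(
                self.matrix, self.go_annotation, self.min_peptides
            )
        except Exception as exc:  # pragma: no cover - defensive relabelling
            raise PipelineError("filter", str(exc)) from exc

        try:
            cfg = ImputeConfig(self.impute.width, self.impute.downshift, True, seed)
            log2 = log2_and_impute(filtered, cfg)
        except Exception as exc:
            raise PipelineError("impute", str(exc)) from exc

        try:
            diff = {
                ko: differential_test(
                    log2, design.wt, design.ko_samples(ko), self.alpha
                )
                for ko in design.ko
            }
            clone_fc = per_clone_fold_changes(log2, design.wt, design.ko)
        except Exception as exc:
            raise PipelineError("test", str(exc)) from exc

        motif_ann = candidates = enr = rescreened = None
        if self.sequences is not None:
            try:
                groups = [
                    (gid, filtered.meta.loc[gid, "members"])
                    for gid in filtered.group_ids
                ]
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    motif_ann = annotate_groups(groups, self.sequences)
                positive = motif_positive_groups(motif_ann)
                candidates = select_candidates(diff, positive)
            except Exception as exc:
                raise PipelineError("motif", str(exc)) from exc

        if candidates is not None and self.domain_annotation is not None:
            try:
                background = set(filtered.group_ids)
                members = dict(filtered.meta["members"])
                enr = fisher_domain_enrichment(
                    set(candidates.union),
                    background,
                    self.domain_annotation,
                    members=members,
                    alpha=self.alpha,
                )
                rescreened = rescreen_domain(
                    background,
                    self.domain_annotation,
                    self.rescreen_domain_name,
                    members=members,
                )
            except Exception as exc:
                raise PipelineError("enrich", str(exc)) from exc

        return ScreenResults(
            filter_report=report,
            log2_matrix=log2,
            differential=diff,
            clone_fold_changes=clone_fc,
            motif_annotations=motif_ann,
            candidates=candidates,
            enrichment=enr,
            rescreen=rescreened,
            alpha=self.alpha,
            seed=seed,
            config_hash=config_hash,
        )


def run_pipeline(cfg: cio.PipelineConfig, outdir: str) -> ScreenResults:
    """Run the screen from a config and write the result bundle.

    Writes results.tsv, filter_report.json, enrichment.tsv, volcano_<KO>.tsv
    and provenance.json into ``outdir``.  Reruns with identical config hash
    and seed produce byte-identical outputs.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    if not Path(cfg.annotation).exists():
        raise PipelineError("config", f"annotation file not found: {cfg.annotation}")
    if not Path(cfg.protein_groups).exists():
        raise PipelineError("config", f"protein groups file not found: {cfg.protein_groups}")
    model = SecretomeScreen.from_files(
        cfg.protein_groups,
        cfg.annotation,
        design=cfg.design,
        fasta=cfg.fasta,
        min_peptides=cfg.min_peptides,
        alpha=cfg.alpha,
        impute=cfg.impute,
    )
    results = model.fit(seed=cfg.seed, config_hash=cfg.config_hash())

    results.results_table().to_csv(out / "results.tsv", sep="\t")
    with open(out / "filter_report.json", "w", encoding="utf-8") as fh:
        json.dump(results.filter_report.as_dict(), fh, indent=1, sort_keys=True)
    if results.enrichment is not None:
        pd.DataFrame(
            [
                {
                    "domain": r.domain, "k": r.k, "n": r.n, "K": r.K, "N": r.N,
                    "odds_ratio": r.odds_ratio, "p": r.p,
                }
                for r in results.enrichment
            ]
        ).to_csv(out / "enrichment.tsv", sep="\t", index=False)
    for ko, res in results.differential.items():
        res.table.to_csv(out / f"volcano_{ko}.tsv", sep="\t")
    from . import __version__

    with open(out / "provenance.json", "w", encoding="utf-8") as fh:
        json.dump(
            {
                "package": "cmannose",
                "version": __version__,
                "seed": cfg.seed,
                "config_hash": cfg.config_hash(),
                "config": cfg.to_dict(),
            },
            fh,
            indent=1,
            sort_keys=True,
        )
    return results
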