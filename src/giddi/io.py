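"""Readers and writers for the pipeline's tab-separated input files.

All inputs are plain TSV with header rows (plus one FASTA file for target
sequences): a MedDRA hierarchy path table, long-format drug→PT annotation
tables, a drug→target-gene table with a companion FASTA of protein
sequences, an allele-level genetic-interaction table, a human→model-organism
homology table, and labeled drug-pair tables.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import SeqIO

from .align import TargetSet
from .gi import GiMeasurement, measurements_from_frame
from .meddra import AnnotationProfile, MeddraHierarchy, profiles_from_frames
from .pairs import SplitPlan, canonical_pair


def _read_tsv(path, required: tuple[str, ...]) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(required) - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return frame


def read_hierarchy(path) -> MeddraHierarchy:
    return MeddraHierarchy.from_frame(
        _read_tsv(path, ("pt_id", "hlt_id", "hlgt_id", "soc_id"))
    )


def read_annotations(indications_path, side_effects_path) -> dict[str, AnnotationProfile]:
    ind = _read_tsv(indications_path, ("drug_id", "pt_id"))
    se = _read_tsv(side_effects_path, ("drug_id", "pt_id"))
    return profiles_from_frames(ind, se)


def read_targets(drugs_path, fasta_path) -> dict[str, TargetSet]:
    """Drug→target map from a (drug_id, gene_id) table plus a gene FASTA."""
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    table = _read_tsv(drugs_path, ("drug_id", "gene_id"))
    by_drug: dict[str, dict[str, str]] = {}
    for drug, gene in table[["drug_id", "gene_id"]].itertuples(index=False):
        if gene not in seqs:
            raise ValueError(f"gene {gene!r} has no sequence in {fasta_path}")
        by_drug.setdefault(str(drug), {})[str(gene)] = seqs[gene]
    return {d: TargetSet(d, genes) for d, genes in by_drug.items()}


def read_gi_table(path) -> list[GiMeasurement]:
    frame = _read_tsv(path, ("gene_a", "gene_b", "score", "p_value"))
    return measurements_from_frame(frame)


def read_homologs(path) -> dict[str, frozenset[str]]:
    frame = _read_tsv(path, ("human_gene", "model_gene"))
    hmap: dict[str, set[str]] = {}
    for human, model in frame[["human_gene", "model_gene"]].itertuples(index=False):
        hmap.setdefault(str(human), set()).add(str(model))
    return {g: frozenset(s) for g, s in hmap.items()}


def read_label_pairs(path) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """(positives, exclusions) from a drug_a/drug_b/label table.

    Label 1 marks an adversely interacting pair; label 0 marks an exclusion
    (a pair with interaction evidence too ambiguous to use as a negative).
    """
    frame = _read_tsv(path, ("drug_a", "drug_b", "label"))
    positives, exclusions = [], []
    for a, b, lab in frame[["drug_a", "drug_b", "label"]].itertuples(index=False):
        pair = canonical_pair(str(a), str(b))
        (positives if int(lab) == 1 else exclusions).append(pair)
    return positives, exclusions


def write_features(frame: pd.DataFrame, path, metadata: Mapping | None = None) -> None:
    frame.to_csv(path, sep="\t", index=True)
    if metadata is not None:
        Path(str(path) + ".meta.json").write_text(json.dumps(metadata, indent=2))


def read_features(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", index_col=["drug_a", "drug_b"])
    return frame.astype(float)


def write_split(plan: SplitPlan, path) -> None:
    Path(path).write_text(json.dumps(plan.to_dict(), indent=2))


def write_predictions(ranked: pd.DataFrame, path) -> None:
    out = ranked.copy()
    out["probability"] = out["probability"].map(lambda p: f"{p:.6f}")
    out.to_csv(path, sep="\t", index=False)
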