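"""Readers and writers for the plain-text table dialects used by the CLI.

All genomic coordinates are 0-based half-open.  Everything is TSV/CSV/JSON;
no binary formats.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .ccf import CopyNumberProfile, MutationTable
from .synthetic import IncidenceCohort

MUTATION_COLUMNS = [
    "patient", "sample", "chrom", "pos", "ref", "alt", "alt_reads", "total_reads", "context",
]
CN_COLUMNS = ["patient", "sample", "chrom", "start", "end", "major_cn", "minor_cn", "purity"]


def write_mutations(table: MutationTable, path) -> None:
    df = table.df.copy()
    if "mutation_id" not in df.columns:
        raise ValueError("mutation table lacks mutation_id")
    cols = ["mutation_id"] + [c for c in MUTATION_COLUMNS if c in df.columns]
    df[cols].to_csv(path, sep="\t", index=False)


def read_mutations(path) -> MutationTable:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return MutationTable(df).validate()


def write_cn_segments(cn: CopyNumberProfile, path) -> None:
    cols = [c for c in CN_COLUMNS if c in cn.df.columns]
    cn.df[cols].to_csv(path, sep="\t", index=False)


def read_cn_segments(path) -> CopyNumberProfile:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return CopyNumberProfile(df).validate()


def write_incidence(cohort: IncidenceCohort, path) -> None:
    cohort.df.to_csv(path, index=False)


def read_incidence(path) -> IncidenceCohort:
    df = pd.read_csv(path)
    df["censored"] = df["censored"].astype(bool)
    return IncidenceCohort(df).validate()


def read_burdens(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_burdens(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())


def _jsonable(obj):
    try:
        import numpy as np

        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
    except ImportError:  # pragma: no cover
        pass
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_cds_fasta(path) -> str:
    """First record of a FASTA file as an upper-case string."""
    from Bio import SeqIO

    record = next(SeqIO.parse(str(path), "fasta"))
    return str(record.seq).upper()


def read_spectrum_tsv(path) -> dict:
    """Spectrum TSV with columns class (e.g. ``ACA>T``) and count."""
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["class"], df["count"].astype(float)))


def read_context_counts_tsv(path) -> dict:
    """Context-counts TSV with columns context and sites."""
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["context"], df["sites"].astype(float)))


def read_driver_set_tsv(path):
    """Driver set TSV with columns consequence and protein_change.

    Rows with consequence start_lost / stop_lost / stop_gained / indel enable
    those classes; rows with consequence missense list admissible protein
    changes like ``P81S`` (position + alternate residue).
    """
    from .driver_rate import DriverConsequenceSet

    df = pd.read_csv(path, sep="\t")
    flags = set(df["consequence"])
    missense = set()
    for change in df.loc[df["consequence"] == "missense", "protein_change"].dropna():
        pos = int("".join(ch for ch in change[1:-1] if ch.isdigit()))
        missense.add((pos, change[-1]))
    return DriverConsequenceSet(
        start_lost="start_lost" in flags,
        stop_lost="stop_lost" in flags,
        stop_gained="stop_gained" in flags,
        missense=frozenset(missense),
        indels_in_cds="indel" in flags,
    )


def mutations_from_vcf(path, samples=None) -> MutationTable:
    """Optional VCF ingestion: FORMAT AD fields become alt/total counts.

    Requires cyvcf2 (not a hard dependency).  Multi-allelic records use the
    first alternate allele.
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("VCF ingestion requires cyvcf2") from exc

    vcf = VCF(str(path))
    names = samples or list(vcf.samples)
    rows = []
    for var in vcf:
        mut_id = f"{var.CHROM}:{var.POS - 1}:{var.REF}:{var.ALT[0]}"
        ad = var.format("AD")
        for i, sample in enumerate(vcf.samples):
            if sample not in names:
                continue
            ref_d, alt_d = int(ad[i][0]), int(ad[i][1])
            rows.append(
                {
                    "mutation_id": mut_id,
                    "sample": sample,
                    "chrom": var.CHROM,
                    "pos": var.POS - 1,
                    "ref": var.REF,
                    "alt": var.ALT[0],
                    "alt_reads": max(alt_d, 0),
                    "total_reads": max(ref_d, 0) + max(alt_d, 0),
                }
            )
    return MutationTable(pd.DataFrame.from_records(rows)).validate()
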