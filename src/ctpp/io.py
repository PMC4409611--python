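"""File formats: FASTA templates, JSON assays, TSV bands / genotypes / calls.

All tabular files are tab-separated with a header row; assays are JSON.
Readers fail with line-numbered messages on malformed records; every
writer/reader pair round-trips losslessly on canonical form.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .design import CtppAssay, Primer, SnpLocus
from .insilico import BandObservation, GenotypeCall
from .seq import VALID_BASES, SequenceError
from .thermo import ThermoConditions


class ParseError(ValueError):
    """Malformed input file; message carries the file and line number."""


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read named DNA sequences, rejecting non-ACGT characters.

    Returns an ordered mapping of record id to uppercase sequence. The
    strict alphabet matches the rest of the package: degenerate codes in a
    template would silently break allele-specific matching.
    """
    path = Path(path)
    # Pre-scan raw lines so alphabet errors carry a line number.
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith((">", ";")):
                continue
            bad = set(stripped.upper()) - VALID_BASES
            if bad:
                raise ParseError(
                    f"{path}:{lineno}: invalid sequence characters {sorted(bad)}"
                )
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    return records


def write_fasta(path: str | Path, sequences: dict[str, str] | Iterable[tuple[str, str]],
                description: str = "") -> None:
    items = sequences.items() if isinstance(sequences, dict) else sequences
    records = [
        SeqRecord(Seq(seq), id=name, description=description) for name, seq in items
    ]
    SeqIO.write(records, str(path), "fasta")


def assay_to_dict(assay: CtppAssay) -> dict:
    return {
        "label": assay.label,
        "notes": assay.notes,
        "locus": {
            "label": assay.locus.label,
            "template": assay.locus.template,
            "snp_offset": assay.locus.snp_offset,
            "allele_x": assay.locus.allele_x,
            "allele_y": assay.locus.allele_y,
        },
        "primers": {
            p.role: {"seq": p.seq, "start": p.start} for p in assay.primers
        },
        "conditions": assay.conditions.to_dict(),
    }


def assay_from_dict(d: dict) -> CtppAssay:
    try:
        locus = SnpLocus(
            template=d["locus"]["template"],
            snp_offset=d["locus"]["snp_offset"],
            allele_x=d["locus"]["allele_x"],
            allele_y=d["locus"]["allele_y"],
            label=d["locus"].get("label", ""),
        )
        primers = {
            role: Primer(seq=spec["seq"], role=role, start=spec["start"])
            for role, spec in d["primers"].items()
        }
        return CtppAssay(
            f1=primers["F1"],
            r1=primers["R1"],
            f2=primers["F2"],
            r2=primers["R2"],
            locus=locus,
            conditions=ThermoConditions.from_dict(
                d.get("conditions", ThermoConditions().to_dict())
            ),
            label=d.get("label", ""),
            notes=d.get("notes", ""),
        )
    except KeyError as exc:
        raise ParseError(f"assay JSON missing field {exc}") from exc


def read_assay_json(path: str | Path) -> CtppAssay:
    with open(path) as fh:
        try:
            d = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ParseError(f"{path}:{exc.lineno}: {exc.msg}") from exc
    return assay_from_dict(d)


def write_assay_json(path: str | Path, assay: CtppAssay) -> None:
    with open(path, "w") as fh:
        json.dump(assay_to_dict(assay), fh, indent=2)
        fh.write("\n")


def read_bands_tsv(path: str | Path) -> list[BandObservation]:
    """Read per-sample band observations (columns: sample_id, sizes).

    ``sizes`` is a comma-separated list of integer bp values; an empty
    field is a lane with no visible bands.
    """
    path = Path(path)
    df = _read_tsv(path, required={"sample_id", "sizes"})
    observations = []
    for row in df.itertuples():
        raw = "" if pd.isna(row.sizes) else str(row.sizes).strip()
        try:
            sizes = tuple(int(tok) for tok in raw.split(",") if tok.strip())
        except ValueError as exc:
            raise ParseError(
                f"{path}:{row.Index + 2}: malformed sizes field {raw!r}"
            ) from exc
        try:
            observations.append(
                BandObservation(sample_id=str(row.sample_id), sizes=sizes)
            )
        except ValueError as exc:
            raise ParseError(f"{path}:{row.Index + 2}: {exc}") from exc
    return observations


def write_bands_tsv(path: str | Path, observations: Sequence[BandObservation]) -> None:
    df = pd.DataFrame(
        {
            "sample_id": [o.sample_id for o in observations],
            "sizes": [",".join(str(s) for s in o.sizes) for o in observations],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_genotypes_tsv(path: str | Path) -> pd.DataFrame:
    """Read a genotype table (columns: sample_id, genotype)."""
    path = Path(path)
    df = _read_tsv(path, required={"sample_id", "genotype"})
    valid = {"XX", "XY", "YY", "NO_CALL"}
    for row in df.itertuples():
        if str(row.genotype) not in valid:
            raise ParseError(
                f"{path}:{row.Index + 2}: genotype {row.genotype!r} not one of "
                + "/".join(sorted(valid))
            )
    df["sample_id"] = df["sample_id"].astype(str)
    return df[["sample_id", "genotype"]]


def write_genotypes_tsv(path: str | Path, table: pd.DataFrame) -> None:
    table[["sample_id", "genotype"]].to_csv(path, sep="\t", index=False)


def calls_to_frame(calls: Sequence[GenotypeCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [c.sample_id for c in calls],
            "genotype": [c.call for c in calls],
            "reason": [c.reason for c in calls],
        }
    )


def write_calls_tsv(path: str | Path, calls: Sequence[GenotypeCall]) -> None:
    calls_to_frame(calls).to_csv(path, sep="\t", index=False)


def read_calls_tsv(path: str | Path) -> list[GenotypeCall]:
    df = read_genotypes_tsv(path)
    return [
        GenotypeCall(sample_id=row.sample_id, call=row.genotype)
        for row in df.itertuples()
    ]


def _read_tsv(path: Path, required: set[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}:1: empty file") from exc
    missing = required - set(df.columns)
    if missing:
        raise ParseError(
            f"{path}:1: missing required column(s) {sorted(missing)}"
        )
    return df
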