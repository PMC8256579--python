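"""Assembling assays from colony sequences / mutation tables plus metadata."""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import pandas as pd
from Bio import SeqIO

from .calling import call_events, read_mutation_table
from .events import MutantColony
from .metrics import AnimalAssay
from .reference import ReferenceGene

METADATA_COLUMNS = (
    "animal_id",
    "group_id",
    "genotype",
    "dose_g_per_l",
    "sex",
    "titer",
    "mutant_count",
)


def read_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("animal_id", "group_id", "titer") if c not in df.columns]
    if missing:
        raise ValueError(f"metadata is missing columns {missing}")
    df["animal_id"] = df["animal_id"].astype(str)
    return df


def colonies_from_fasta(
    fasta_path: str | Path,
    ref: ReferenceGene,
    id_delimiter: str = "|",
    min_identity: float = 0.9,
) -> list[MutantColony]:
    """Call events for every colony record (ID format ``animalID|colonyID``)."""
    colonies = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if id_delimiter not in rec.id:
            raise ValueError(
                f"record {rec.id!r} lacks the {id_delimiter!r} animal/colony delimiter"
            )
        animal_id, colony_id = rec.id.split(id_delimiter, 1)
        events = call_events(ref, str(rec.seq), min_identity=min_identity)
        colonies.append(
            MutantColony(animal_id=animal_id, colony_id=colony_id, events=tuple(events))
        )
    return colonies


def load_assays(
    metadata_path: str | Path,
    ref: ReferenceGene,
    fasta_path: Optional[str | Path] = None,
    table_path: Optional[str | Path] = None,
    id_delimiter: str = "|",
    min_identity: float = 0.9,
) -> list[AnimalAssay]:
    """Build per-animal assays from metadata plus colony FASTA or table.

    Every colony's animal must appear in the metadata; animals without
    colonies get an empty colony list. ``mutant_count`` defaults to the
    number of colonies when the metadata lacks that column.
    """
    if (fasta_path is None) == (table_path is None):
        raise ValueError("provide exactly one of fasta_path or table_path")
    if fasta_path is not None:
        colonies = colonies_from_fasta(
            fasta_path, ref, id_delimiter=id_delimiter, min_identity=min_identity
        )
    else:
        colonies = read_mutation_table(table_path, ref)
    by_animal: dict[str, list[MutantColony]] = {}
    for colony in colonies:
        by_animal.setdefault(colony.animal_id, []).append(colony)
    meta = read_metadata(metadata_path)
    known = set(meta["animal_id"])
    unknown = sorted(set(by_animal) - known)
    if unknown:
        raise ValueError(f"colonies reference animals missing from metadata: {unknown}")
    assays = []
    for row in meta.itertuples(index=False):
        animal_colonies = tuple(by_animal.get(row.animal_id, []))
        mutant_count = (
            int(row.mutant_count)
            if "mutant_count" in meta.columns and not pd.isna(row.mutant_count)
            else len(animal_colonies)
        )
        assays.append(
            AnimalAssay(
                animal_id=row.animal_id,
                group_id=str(row.group_id),
                genotype=str(getattr(row, "genotype", "unknown")),
                dose_g_per_l=float(getattr(row, "dose_g_per_l", 0.0)),
                sex=str(getattr(row, "sex", "unknown")),
                titer=int(row.titer),
                mutant_count=mutant_count,
                colonies=animal_colonies,
            )
        )
    return assays
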