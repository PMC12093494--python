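"""Per-organism aggregation: genome statistics and CAZyme count vectors.

The central genome-level statistic is the percentage of annotated coding
sequences (CDS) that carry at least one CAZyme domain,

    %CAZyme CDS = 100 * cazyme_cds / total_cds.

Counting is protein-level throughout: a protein increments a CAZyme category
once if any of its retained domains belongs to it (a GH+CBM protein counts
toward both GH and CBM), and counts once toward every substrate reachable
from any of its families, so bifunctional families propagate to all their
substrates.  Domain-instance tallies are exported alongside for family-level
abundance tables.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Union

import pandas as pd

from .architecture import Granularity, ProteinArchitecture
from .vocab import Category, Substrate, SubstrateMap

HABITATS = ("soil", "marine", "other")

METADATA_COLUMNS = [
    "tag", "name", "suborder", "family", "genus", "habitat",
    "genome_size_bp", "total_cds",
]


@dataclass
class OrganismProfile:
    """Taxonomy, genome statistics and CAZyme count vectors for one organism."""

    organism_tag: str
    name: str
    suborder: str
    family: str
    genus: str
    habitat: str
    genome_size_bp: int
    total_cds: int
    cazyme_cds: int
    category_counts: dict[str, int]
    family_counts: dict[str, int]
    substrate_counts: dict[str, int]
    gc_percent: float | None = None

    def __post_init__(self) -> None:
        if self.total_cds <= 0:
            raise ValueError(f"{self.organism_tag}: total_cds must be positive")
        if not (0 <= self.cazyme_cds <= self.total_cds):
            raise ValueError(
                f"{self.organism_tag}: cazyme_cds {self.cazyme_cds} outside "
                f"[0, total_cds={self.total_cds}]"
            )
        if self.habitat not in HABITATS:
            raise ValueError(f"{self.organism_tag}: unknown habitat {self.habitat!r}")

    @property
    def pct_cazyme(self) -> float:
        return percent_cazyme(self.cazyme_cds, self.total_cds)


def percent_cazyme(cazyme_cds: int, total_cds: int) -> float:
    """Percentage of CDS carrying at least one CAZyme domain."""
    if total_cds <= 0:
        raise ValueError("total_cds must be positive")
    if not (0 <= cazyme_cds <= total_cds):
        raise ValueError("require 0 <= cazyme_cds <= total_cds")
    return 100.0 * cazyme_cds / total_cds


def gc_percent(sequence: str) -> float:
    """GC content of a nucleotide sequence, ambiguity codes excluded.

    Characters outside A/C/G/T (case-insensitive) are excluded from both
    numerator and denominator; a sequence with no unambiguous bases is
    rejected.
    """
    if not sequence:
        raise ValueError("empty sequence")
    counts = Counter(sequence.upper())
    acgt = counts["A"] + counts["C"] + counts["G"] + counts["T"]
    if acgt == 0:
        raise ValueError("sequence contains no unambiguous A/C/G/T bases")
    return 100.0 * (counts["G"] + counts["C"]) / acgt


def category_counts(architectures: Iterable[ProteinArchitecture]) -> dict[str, int]:
    """Proteins per CAZyme category (a protein counts once per category)."""
    counts = {c.value: 0 for c in Category}
    for arch in architectures:
        for cat in {d.category for d in arch.domains}:
            counts[cat.value] += 1
    return counts


def substrate_counts(
    architectures: Iterable[ProteinArchitecture], smap: SubstrateMap
) -> dict[str, int]:
    """Proteins per degradable substrate (a protein counts once per substrate)."""
    counts = {s.value: 0 for s in Substrate}
    for arch in architectures:
        reachable: set[Substrate] = set()
        for fam in set(arch.domains):
            reachable |= smap.substrates_for(fam)
        for s in reachable:
            counts[s.value] += 1
    return counts


def family_counts(
    architectures: Iterable[ProteinArchitecture],
    *,
    granularity: Granularity = "family",
    instance_level: bool = False,
) -> dict[str, int]:
    """Per-family tallies, protein-level by default.

    With ``granularity="family"`` subfamily labels count toward their parent
    family; ``"subfamily"`` keeps them distinct.  ``instance_level=True``
    counts domain instances instead of proteins.
    """
    counts: Counter[str] = Counter()
    for arch in architectures:
        if instance_level:
            for d in arch.domains:
                key = (d.parent if granularity == "family" else d).canonical
                counts[key] += 1
        else:
            for fam in arch.families(granularity):
                counts[fam.canonical] += 1
    return dict(counts)


def build_profile(
    metadata_row: Mapping[str, object],
    architectures: Iterable[ProteinArchitecture],
    smap: SubstrateMap,
) -> OrganismProfile:
    """Assemble one organism's profile from metadata and its architectures.

    ``metadata_row`` needs tag, name, suborder, family, genus, habitat,
    genome_size_bp and total_cds (see :func:`read_metadata`); the
    architectures are that organism's filtered proteins.
    """
    archs = list(architectures)
    row = dict(metadata_row)
    missing = [c for c in METADATA_COLUMNS if c not in row or pd.isna(row[c])]
    if missing:
        raise ValueError(f"metadata for {row.get('tag', '?')} missing {missing}")
    tags = {a.organism_tag for a in archs}
    if tags and tags != {str(row["tag"])}:
        raise ValueError(
            f"architectures tagged {sorted(tags)} do not match metadata tag {row['tag']!r}"
        )
    gc = row.get("gc_percent")
    return OrganismProfile(
        organism_tag=str(row["tag"]),
        name=str(row["name"]),
        suborder=str(row["suborder"]),
        family=str(row["family"]),
        genus=str(row["genus"]),
        habitat=str(row["habitat"]),
        genome_size_bp=int(row["genome_size_bp"]),
        total_cds=int(row["total_cds"]),
        cazyme_cds=len(archs),
        category_counts=category_counts(archs),
        family_counts=family_counts(archs),
        substrate_counts=substrate_counts(archs, smap),
        gc_percent=float(gc) if gc is not None and not pd.isna(gc) else None,
    )


def read_metadata(path: Union[str, Path]) -> pd.DataFrame:
    """Read the per-organism metadata TSV.

    Required columns: tag, name, suborder, family, genus, habitat,
    genome_size_bp, total_cds.  Optional: gc_percent, fasta_path, gff_path.
    When total_cds is missing but gff_path is present, the CDS count is
    derived from the GFF3 file; likewise gc_percent from fasta_path.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"tag": str})
    missing = [c for c in METADATA_COLUMNS if c != "total_cds" and c not in df.columns]
    if missing:
        raise ValueError(f"metadata {path} missing columns {missing}")
    if "total_cds" not in df.columns:
        df["total_cds"] = pd.NA
    base = Path(path).parent
    for i, row in df.iterrows():
        if pd.isna(row["total_cds"]):
            gff = row.get("gff_path")
            if gff is None or pd.isna(gff):
                raise ValueError(
                    f"metadata row for {row['tag']}: total_cds missing and no gff_path"
                )
            df.at[i, "total_cds"] = count_cds_gff3(_resolve(base, str(gff)))
        if "gc_percent" in df.columns and pd.isna(row.get("gc_percent")):
            fasta = row.get("fasta_path")
            if fasta is not None and not pd.isna(fasta):
                df.at[i, "gc_percent"] = genome_gc_percent(_resolve(base, str(fasta)))
    df["total_cds"] = df["total_cds"].astype(int)
    return df


def _resolve(base: Path, p: str) -> Path:
    path = Path(p)
    return path if path.is_absolute() else base / path


def count_cds_gff3(path: Union[str, Path]) -> int:
    """Count distinct CDS features in a GFF3 file.

    Features of type ``CDS`` are counted by distinct ``ID`` attribute (a
    multi-exon CDS split over several lines counts once); CDS lines without
    an ID each count individually.
    """
    ids: set[str] = set()
    anonymous = 0
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 8 or fields[2] != "CDS":
                continue
            attrs = fields[8] if len(fields) > 8 else ""
            cds_id = None
            for kv in attrs.split(";"):
                if kv.startswith("ID="):
                    cds_id = kv[3:]
                    break
            if cds_id:
                ids.add(cds_id)
            else:
                anonymous += 1
    return len(ids) + anonymous


def genome_gc_percent(path: Union[str, Path]) -> float:
    """GC content of a (multi-)FASTA genome."""
    from Bio import SeqIO

    seqs = [str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")]
    if not seqs:
        raise ValueError(f"no sequences in {path}")
    return gc_percent("".join(seqs))


def profiles_to_frame(profiles: Iterable[OrganismProfile]) -> pd.DataFrame:
    """Flatten profiles into one organisms x columns table.

    Columns: metadata, cazyme_cds, pct_cazyme, then one ``n_<category>``
    column per CAZyme category and one ``n_<substrate>`` column per
    substrate.
    """
    rows = []
    for p in profiles:
        row: dict[str, object] = {
            "tag": p.organism_tag,
            "name": p.name,
            "suborder": p.suborder,
            "family": p.family,
            "genus": p.genus,
            "habitat": p.habitat,
            "genome_size_bp": p.genome_size_bp,
            "gc_percent": p.gc_percent,
            "total_cds": p.total_cds,
            "cazyme_cds": p.cazyme_cds,
            "pct_cazyme": p.pct_cazyme,
        }
        for cat in Category:
            row[f"n_{cat.value}"] = p.category_counts.get(cat.value, 0)
        for sub in Substrate:
            row[f"n_{sub.value}"] = p.substrate_counts.get(sub.value, 0)
        rows.append(row)
    return pd.DataFrame(rows)


def family_count_matrix(
    profiles: Iterable[OrganismProfile]
) -> pd.DataFrame:
    """Organisms x families protein-count matrix (zeros where absent)."""
    profiles = list(profiles)
    fams = sorted({f for p in profiles for f in p.family_counts})
    data = {
        p.organism_tag: [p.family_counts.get(f, 0) for f in fams] for p in profiles
    }
    return pd.DataFrame(data, index=fams).T
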