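"""Reading and writing HMMER3 ``--domtblout`` domain tables.

One data line per domain match, whitespace-delimited, ``#`` comment lines.
The default column orientation places the protein in the target columns
(field 0) and the CAZyme HMM in the query columns (name field 3, profile
length field 5), with per-domain statistics at the standard positions:
c-Evalue 11, i-Evalue 12, score 13, hmm coordinates 15-16, alignment
coordinates 17-18, envelope 19-20.  Files whose *target* is the HMM (the
native hmmscan layout) are read with ``orientation="target-hmm"``.

Each retained match records the covered fraction of the HMM profile,

    coverage = (hmm_to - hmm_from + 1) / hmm_length,

the quantity downstream quality filtering thresholds on.  All coordinates are
1-based inclusive, the HMMER convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Union

from .vocab import FamilyLabel, parse_family_label

Orientation = Literal["query-hmm", "target-hmm"]

#: minimum fields on a domtblout data line (the trailing description is free text)
_MIN_FIELDS = 23


@dataclass(frozen=True)
class DomainHit:
    """One filtered hmmscan domain match with coordinates and statistics."""

    protein_id: str
    organism_tag: str
    family: FamilyLabel
    hmm_length: int
    hmm_from: int
    hmm_to: int
    ali_from: int
    ali_to: int
    env_from: int
    env_to: int
    full_seq_evalue: float
    dom_ievalue: float
    dom_score: float
    coverage: float = field(init=False)

    def __post_init__(self) -> None:
        if self.hmm_length <= 0:
            raise ValueError(f"{self.protein_id}: hmm_length must be positive")
        if not (1 <= self.hmm_from <= self.hmm_to <= self.hmm_length):
            raise ValueError(
                f"{self.protein_id}: require 1 <= hmm_from <= hmm_to <= hmm_length, "
                f"got {self.hmm_from}..{self.hmm_to} / {self.hmm_length}"
            )
        if not (1 <= self.ali_from <= self.ali_to):
            raise ValueError(f"{self.protein_id}: require 1 <= ali_from <= ali_to")
        if not (1 <= self.env_from <= self.env_to):
            raise ValueError(f"{self.protein_id}: require 1 <= env_from <= env_to")
        if self.full_seq_evalue < 0 or self.dom_ievalue < 0:
            raise ValueError(f"{self.protein_id}: e-values must be non-negative")
        object.__setattr__(
            self, "coverage", (self.hmm_to - self.hmm_from + 1) / self.hmm_length
        )

    @property
    def ali_length(self) -> int:
        return self.ali_to - self.ali_from + 1


def _parse_data_line(
    fields: list[str], organism_tag: str, orientation: Orientation, where: str
) -> DomainHit:
    if orientation == "query-hmm":
        protein_id, hmm_name = fields[0], fields[3]
    else:
        protein_id, hmm_name = fields[3], fields[0]
    try:
        family = parse_family_label(hmm_name)
    except ValueError as exc:
        raise ValueError(f"{where}: {exc}") from exc
    try:
        # qlen col 5 holds the HMM profile length in the query-hmm orientation;
        # in target-hmm files it is tlen (col 2).
        hmm_length = int(fields[5] if orientation == "query-hmm" else fields[2])
        full_e = float(fields[6])
        ieval = float(fields[12])
        score = float(fields[13])
        hmm_from, hmm_to = int(fields[15]), int(fields[16])
        ali_from, ali_to = int(fields[17]), int(fields[18])
        env_from, env_to = int(fields[19]), int(fields[20])
    except ValueError as exc:
        raise ValueError(f"{where}: non-numeric field ({exc})") from exc
    try:
        return DomainHit(
            protein_id=protein_id,
            organism_tag=organism_tag,
            family=family,
            hmm_length=hmm_length,
            hmm_from=hmm_from,
            hmm_to=hmm_to,
            ali_from=ali_from,
            ali_to=ali_to,
            env_from=env_from,
            env_to=env_to,
            full_seq_evalue=full_e,
            dom_ievalue=ieval,
            dom_score=score,
        )
    except ValueError as exc:
        raise ValueError(f"{where}: {exc}") from exc


def read_domtblout(
    path: Union[str, Path],
    organism_tag: str | None = None,
    *,
    orientation: Orientation = "query-hmm",
) -> list[DomainHit]:
    """Parse a domtblout file into :class:`DomainHit` records.

    ``#``-prefixed header/footer lines are skipped.  Every other line must
    split into at least 23 whitespace-separated fields (extra fields form the
    free-text description); anything shorter, or any non-numeric coordinate,
    fails loudly with the line number — no partial parses.  The organism tag
    defaults to the filename stem.
    """
    path = Path(path)
    if organism_tag is None:
        organism_tag = path.stem
    hits: list[DomainHit] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.split()
            if len(fields) < _MIN_FIELDS:
                raise ValueError(
                    f"{path}:{lineno}: expected >= {_MIN_FIELDS} fields, got {len(fields)}"
                )
            hits.append(
                _parse_data_line(fields, organism_tag, orientation, f"{path}:{lineno}")
            )
    return hits


_HEADER = (
    "#{:<29s} {:>10s} {:>5s} {:<20s} {:>10s} {:>5s} {:>9s} {:>6s} {:>5s} {:>3s} "
    "{:>3s} {:>9s} {:>9s} {:>6s} {:>5s} {:>5s} {:>5s} {:>5s} {:>5s} {:>5s} {:>5s} "
    "{:>4s} {:s}"
).format(
    "target name", "accession", "tlen", "query name", "accession", "qlen",
    "E-value", "score", "bias", "#", "of", "c-Evalue", "i-Evalue", "score",
    "bias", "from", "to", "from", "to", "from", "to", "acc", "description of target",
)


def write_domtblout(
    hits: Iterable[DomainHit],
    path: Union[str, Path],
    *,
    orientation: Orientation = "query-hmm",
) -> Path:
    """Write hits as a syntactically valid domtblout file (one line per hit).

    Domain index/count columns are renumbered per protein; hit invariants are
    enforced by :class:`DomainHit` construction before anything is written.
    The output round-trips through :func:`read_domtblout`.
    """
    path = Path(path)
    hits = list(hits)
    per_protein: dict[str, int] = {}
    for h in hits:
        per_protein[h.protein_id] = per_protein.get(h.protein_id, 0) + 1
    seen: dict[str, int] = {}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_HEADER + "\n")
        fh.write("#" + "-" * (len(_HEADER) - 1) + "\n")
        for h in hits:
            seen[h.protein_id] = seen.get(h.protein_id, 0) + 1
            prot_len = max(h.ali_to, h.env_to)
            if orientation == "query-hmm":
                tname, tacc, tlen = h.protein_id, "-", prot_len
                qname, qacc, qlen = h.family.canonical + ".hmm", "-", h.hmm_length
            else:
                tname, tacc, tlen = h.family.canonical + ".hmm", "-", h.hmm_length
                qname, qacc, qlen = h.protein_id, "-", prot_len
            # e-values and scores are written at full precision (shortest
            # round-trippable repr) so read(write(X)) == X exactly
            fh.write(
                f"{tname:<30s} {tacc:>10s} {tlen:>5d} {qname:<20s} {qacc:>10s} "
                f"{qlen:>5d} {h.full_seq_evalue:>12.17g} {h.dom_score:>10.17g} "
                f"{0.0:>5.1f} {seen[h.protein_id]:>3d} {per_protein[h.protein_id]:>3d} "
                f"{h.dom_ievalue:>12.17g} {h.dom_ievalue:>12.17g} {h.dom_score:>10.17g} "
                f"{0.0:>5.1f} {h.hmm_from:>5d} {h.hmm_to:>5d} {h.ali_from:>5d} "
                f"{h.ali_to:>5d} {h.env_from:>5d} {h.env_to:>5d} {0.90:>4.2f} -\n"
            )
        fh.write("#\n")
    return path


def group_by_protein(hits: Iterable[DomainHit]) -> dict[str, list[DomainHit]]:
    """Group hits by protein_id, preserving input order within each protein."""
    grouped: dict[str, list[DomainHit]] = {}
    for h in hits:
        grouped.setdefault(h.protein_id, []).append(h)
    return grouped
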