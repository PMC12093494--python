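"""CAZyme nomenclature and the substrate -> family map.

Carbohydrate-active enzymes (CAZymes) are classified into six categories:
glycoside hydrolases (GH), glycosyltransferases (GT), polysaccharide lyases
(PL), carbohydrate esterases (CE), auxiliary activities (AA) and
carbohydrate-binding modules (CBM).  Families are numbered within a category
(GH13, CBM50) and may carry a numbered subfamily (GH13_11).  dbCAN HMM names
follow the same scheme with an optional ``.hmm`` suffix.

The :class:`SubstrateMap` links CAZyme families to the polysaccharide
substrates whose degradation they catalyse (cellulose, xylan, lignin, starch,
chitin, dextran, fructan, pectin).  A family may be bifunctional and map to
more than one substrate (GH13 acts on both starch and dextran); subfamily
labels inherit their parent family's substrates.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Union


class Category(str, Enum):
    """The six CAZy categories."""

    GH = "GH"
    GT = "GT"
    PL = "PL"
    CE = "CE"
    AA = "AA"
    CBM = "CBM"


class Substrate(str, Enum):
    """Polysaccharide substrates tracked by the degradation-potential map."""

    CELLULOSE = "cellulose"
    XYLAN = "xylan"
    LIGNIN = "lignin"
    STARCH = "starch"
    CHITIN = "chitin"
    DEXTRAN = "dextran"
    FRUCTAN = "fructan"
    PECTIN = "pectin"


_LABEL_RE = re.compile(r"^(CBM|GH|GT|PL|CE|AA)(\d+)(?:_(\d+))?$")


@dataclass(frozen=True, order=True)
class FamilyLabel:
    """A parsed CAZyme category/family/subfamily identifier.

    Round-trips to its canonical string form: ``GH13_11``, ``CBM50``.
    """

    category: Category
    family_number: int
    subfamily: int | None = None

    def __post_init__(self) -> None:
        if self.family_number <= 0:
            raise ValueError(f"family number must be positive: {self.family_number}")
        if self.subfamily is not None and self.subfamily < 0:
            raise ValueError(f"subfamily must be non-negative: {self.subfamily}")

    @property
    def canonical(self) -> str:
        base = f"{self.category.value}{self.family_number}"
        return base if self.subfamily is None else f"{base}_{self.subfamily}"

    @property
    def parent(self) -> "FamilyLabel":
        """The family-level label, stripping any subfamily."""
        if self.subfamily is None:
            return self
        return FamilyLabel(self.category, self.family_number)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.canonical


def parse_family_label(raw: str) -> FamilyLabel:
    """Parse a dbCAN-style family token (``"GH13_11.hmm"`` -> GH13_11).

    A trailing ``.hmm`` suffix is stripped; the subfamily, if any, follows an
    underscore.  Unknown category prefixes or non-numeric family numbers are
    rejected with the offending token named.
    """
    if not raw or not raw.strip():
        raise ValueError("empty family label")
    token = raw.strip()
    if token.endswith(".hmm"):
        token = token[: -len(".hmm")]
    m = _LABEL_RE.match(token)
    if m is None:
        raise ValueError(f"unrecognised CAZyme family label: {raw!r}")
    cat, fam, sub = m.groups()
    return FamilyLabel(Category(cat), int(fam), int(sub) if sub is not None else None)


@dataclass(frozen=True)
class SubstrateEntry:
    """One substrate/activity row: an enzyme activity with its families."""

    substrate: Substrate
    activity: str
    ec_numbers: tuple[str, ...]
    families: frozenset[FamilyLabel]


@dataclass
class SubstrateMap:
    """Substrate -> activity -> family-set table with bifunctionality support.

    Lookup by family returns the full substrate set; subfamily labels inherit
    the substrates of their parent family.  EC numbers are carried as opaque
    strings used only as annotation keys.
    """

    entries: list[SubstrateEntry] = field(default_factory=list)

    def families_for(self, substrate: Substrate | str) -> frozenset[FamilyLabel]:
        substrate = Substrate(substrate)
        fams: set[FamilyLabel] = set()
        for e in self.entries:
            if e.substrate is substrate:
                fams |= e.families
        return frozenset(fams)

    def substrates_for(self, family: Union[FamilyLabel, str]) -> frozenset[Substrate]:
        """All substrates reachable from *family* (subfamilies inherit)."""
        if isinstance(family, str):
            family = parse_family_label(family)
        keys = {family, family.parent}
        subs: set[Substrate] = set()
        for e in self.entries:
            if keys & set(e.families):
                subs.add(e.substrate)
        return frozenset(subs)

    @property
    def all_families(self) -> frozenset[FamilyLabel]:
        fams: set[FamilyLabel] = set()
        for e in self.entries:
            fams |= e.families
        return frozenset(fams)

    def extend(self, other: "SubstrateMap") -> "SubstrateMap":
        """Return a new map with *other*'s entries appended."""
        return SubstrateMap(entries=list(self.entries) + list(other.entries))


def _fams(*names: str) -> frozenset[FamilyLabel]:
    return frozenset(parse_family_label(n) for n in names)


# Families shared between cellulase and xylanase activity (bifunctional:
# the second substrate recognised by most bifunctional cellulase GH domains).
_CELLULOSE_XYLAN_SHARED = (
    "GH10", "GH1", "GH116", "GH2", "GH3", "GH30", "GH39", "GH51", "GH5", "GH8",
)


def default_substrate_map() -> SubstrateMap:
    """The built-in substrate map.

    Encodes only family-substrate assignments stated in the analysed dataset's
    enzyme curation: six GH families unique to cellulase activity plus the
    cellulose/xylan bifunctional set and the cellulose/chitin-acting GH48;
    xylanase-specific GH and CE families; the lignin-peroxidase-associated AA
    families; amylase, chitinase, dextranase, fructan-exohydrolase and
    pectinase family sets.  A fuller table can be supplied via
    :func:`load_substrate_map`.
    """
    entries = [
        SubstrateEntry(
            Substrate.CELLULOSE, "cellulase (endo/exo)", ("3.2.1.4", "3.2.1.91"),
            _fams("GH6", "GH9", "GH12", "GH44", "GH45", "GH74"),
        ),
        SubstrateEntry(
            Substrate.CELLULOSE, "cellulase/beta-glucosidase (bifunctional with xylanase)",
            ("3.2.1.4", "3.2.1.21"), _fams(*_CELLULOSE_XYLAN_SHARED),
        ),
        SubstrateEntry(
            Substrate.CELLULOSE, "endochitinase-overlapping cellulase", ("3.2.1.4",),
            _fams("GH48"),
        ),
        SubstrateEntry(
            Substrate.XYLAN, "xylanase/beta-xylosidase", ("3.2.1.8", "3.2.1.37"),
            _fams(*_CELLULOSE_XYLAN_SHARED, "GH43", "GH52", "GH67"),
        ),
        SubstrateEntry(
            Substrate.XYLAN, "acetyl xylan esterase / feruloyl esterase",
            ("3.1.1.72", "3.1.1.73"), _fams("CE1", "CE4", "CE7"),
        ),
        SubstrateEntry(
            Substrate.LIGNIN, "laccase", ("1.10.3.2",), _fams("AA1"),
        ),
        SubstrateEntry(
            Substrate.LIGNIN, "lignin peroxidase", ("1.11.1.14",), _fams("AA2"),
        ),
        SubstrateEntry(
            Substrate.STARCH, "alpha-amylase", ("3.2.1.1",),
            _fams("GH13", "GH57", "GH119"),
        ),
        SubstrateEntry(
            Substrate.STARCH, "beta-amylase", ("3.2.1.2",), _fams("GH14"),
        ),
        SubstrateEntry(
            Substrate.STARCH, "gamma-amylase (glucoamylase)", ("3.2.1.3",),
            _fams("GH15", "GH97"),
        ),
        SubstrateEntry(
            Substrate.CHITIN, "endochitinase", ("3.2.1.14",),
            _fams("GH18", "GH19", "GH23", "GH48"),
        ),
        SubstrateEntry(
            Substrate.DEXTRAN, "dextranase", ("3.2.1.11",), _fams("GH66", "GH49"),
        ),
        SubstrateEntry(
            Substrate.DEXTRAN, "glucan-1,6-alpha-D-glucosidase", ("3.2.1.70",),
            _fams("GH13", "GH15"),
        ),
        SubstrateEntry(
            Substrate.DEXTRAN, "glucan-1,6-alpha-isomaltosidase", ("3.2.1.94",),
            _fams("GH27"),
        ),
        SubstrateEntry(
            Substrate.FRUCTAN, "fructan exohydrolase", ("3.2.1.80",), _fams("GH32"),
        ),
        SubstrateEntry(
            Substrate.PECTIN, "pectin methylesterase", ("3.1.1.11",), _fams("CE8"),
        ),
        SubstrateEntry(
            Substrate.PECTIN, "endo-polygalacturonase", ("3.2.1.15",), _fams("GH28"),
        ),
        SubstrateEntry(
            Substrate.PECTIN, "pectin lyase", ("4.2.2.10",), _fams("PL1"),
        ),
    ]
    return SubstrateMap(entries=entries)


def load_substrate_map(path: Union[str, Path], *, extend_default: bool = False) -> SubstrateMap:
    """Load a substrate map from a 4-column TSV.

    Columns: substrate, activity, ec_number, family.  ``#``-comment lines are
    allowed; EC numbers may be ';'-separated; duplicate (substrate, family)
    rows collapse on lookup.  With ``extend_default`` the rows are appended to
    the built-in map rather than replacing it.
    """
    path = Path(path)
    entries: list[SubstrateEntry] = []
    n_rows = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = [p.strip() for p in line.split("\t")]
            if len(parts) < 4:
                raise ValueError(
                    f"{path}:{lineno}: expected 4 tab-separated columns, got {len(parts)}"
                )
            substrate_s, activity, ec_s, family_s = parts[:4]
            if n_rows == 0 and substrate_s.lower() == "substrate":
                continue  # header row
            try:
                substrate = Substrate(substrate_s.lower())
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unknown substrate {substrate_s!r}") from exc
            try:
                fam = parse_family_label(family_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            ecs = tuple(e.strip() for e in ec_s.split(";") if e.strip())
            entries.append(SubstrateEntry(substrate, activity, ecs, frozenset([fam])))
            n_rows += 1
    if not entries:
        raise ValueError(f"substrate map {path} contains no data rows")
    loaded = SubstrateMap(entries=entries)
    return default_substrate_map().extend(loaded) if extend_default else loaded


def write_substrate_map(smap: SubstrateMap, path: Union[str, Path]) -> None:
    """Write a substrate map as the 4-column TSV accepted by the loader."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("substrate\tactivity\tec_number\tfamily\n")
        for e in smap.entries:
            ecs = ";".join(e.ec_numbers)
            for fam in sorted(e.families):
                fh.write(f"{e.substrate.value}\t{e.activity}\t{ecs}\t{fam.canonical}\n")


def packaged_substrate_map_path() -> Path:
    """Path to the TSV shipped with the package (mirrors the built-in map)."""
    return Path(str(resources.files("cazprofiler").joinpath("data/substrate_map.tsv")))
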