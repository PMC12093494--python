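"""Synthetic organisms, proteomes and domain tables with known ground truth.

The generator emulates the statistical structure the comparative analysis
assumes: a 3-suborder / 9-family taxonomy sampled ~70/10/20% across
suborders, genome sizes of roughly 2-16 Mb with CDS counts tightly coupled
to genome size, per-family %CAZyme-CDS targets in the 2-5% range (higher in
Archangiaceae and Myxococcaceae, lowest in the marine Nannocystineae
families), and multi-domain proteins drawn from a pool of realistic
architecture templates (GH23 alone or with CBM50 copies, GH13 subfamilies
with CBM48, GH6+CBM4, CE8 triplicates, GH32 with CBM66 pairs, ...).

Two kinds of decoys exercise the hit filter:

* *overlap decoys* copy a true hit's alignment interval shifted by less than
  half its length, with an e-value three to six orders of magnitude worse —
  removable only by overlap resolution;
* *noise hits* have HMM coverage below the quality threshold — removable
  only by the coverage filter.

Planted domains are spaced so that a decoy can conflict only with its source
hit; with decoys enabled the filter therefore recovers exactly the planted
truth, and with decoys disabled the raw tables already equal it.  Every
quantity the pipeline later measures (architectures, category, family and
substrate counts, %CAZyme CDS) is emitted as ground-truth tables.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .domtblout import DomainHit, write_domtblout
from .vocab import (
    FamilyLabel,
    Substrate,
    SubstrateMap,
    default_substrate_map,
    parse_family_label,
)

#: (suborder, family, members) — 61 organisms, ~70/10/20% suborder split
DEFAULT_TAXONOMY: tuple[tuple[str, str, int], ...] = (
    ("Cystobacterineae", "Myxococcaceae", 26),
    ("Cystobacterineae", "Archangiaceae", 11),
    ("Cystobacterineae", "Anaeromyxobacteraceae", 3),
    ("Cystobacterineae", "Vulgatibacteraceae", 2),
    ("Nannocystineae", "Nannocystaceae", 4),
    ("Nannocystineae", "Kofleriaceae", 2),
    ("Sorangiineae", "Polyangiaceae", 11),
    ("Sorangiineae", "Sandaracinaceae", 1),
    ("Sorangiineae", "Labilitrichaceae", 1),
)

#: family -> (%CAZyme mean, sd); medians echo the observed family medians
DEFAULT_PCT_CAZYME: dict[str, tuple[float, float]] = {
    "Myxococcaceae": (3.7, 0.40),
    "Archangiaceae": (4.44, 0.45),
    "Anaeromyxobacteraceae": (3.0, 0.40),
    "Vulgatibacteraceae": (3.0, 0.30),
    "Nannocystaceae": (2.16, 0.20),
    "Kofleriaceae": (2.3, 0.25),
    "Polyangiaceae": (3.11, 0.50),
    "Sandaracinaceae": (3.0, 0.30),
    "Labilitrichaceae": (3.3, 0.30),
}

#: family -> genome size range (Mb); small-genome outlier families included
DEFAULT_GENOME_MB: dict[str, tuple[float, float]] = {
    "Myxococcaceae": (8.5, 10.5),
    "Archangiaceae": (9.5, 12.5),
    "Anaeromyxobacteraceae": (2.0, 5.0),
    "Vulgatibacteraceae": (4.0, 5.0),
    "Nannocystaceae": (9.0, 10.5),
    "Kofleriaceae": (9.0, 9.6),
    "Polyangiaceae": (9.0, 14.0),
    "Sandaracinaceae": (10.0, 11.0),
    "Labilitrichaceae": (10.0, 11.0),
}

MARINE_SUBORDERS = {"Nannocystineae"}

#: (architecture template, weight) — multi-domain patterns seen in real
#: CAZome architectures; weights set the relative template frequencies
DEFAULT_ARCHITECTURE_POOL: tuple[tuple[tuple[str, ...], float], ...] = (
    (("GH23",), 8.0),
    (("GH23", "CBM50"), 2.0),
    (("GH23", "CBM50", "CBM50"), 1.0),
    (("GT2",), 8.0),
    (("GT4",), 8.0),
    (("GH13_11", "CBM48"), 2.0),
    (("GH13_10", "CBM48"), 1.5),
    (("GH13",), 2.0),
    (("GH6", "CBM4"), 1.0),
    (("GH9", "CBM30"), 1.0),
    (("GH74",), 1.0),
    (("GH5",), 1.5),
    (("GH12",), 0.5),
    (("CE1",), 6.0),
    (("CE4",), 3.0),
    (("CE7",), 1.0),
    (("GH18", "CBM5"), 1.0),
    (("GH19", "CBM50"), 0.5),
    (("GH15",), 1.0),
    (("GH57",), 0.8),
    (("GH97",), 0.5),
    (("GH43",), 1.5),
    (("GH2",), 1.5),
    (("GH3",), 2.0),
    (("GH10",), 1.0),
    (("GH32", "CBM66", "CBM66"), 0.3),
    (("GH32",), 0.2),
    (("CE8", "CE8", "CE8"), 0.1),
    (("GH28",), 0.3),
    (("PL1",), 0.8),
    (("PL1", "CBM13"), 0.2),
    (("AA2",), 0.6),
    (("AA10",), 0.4),
)

#: category medians (GH, GT, PL, CE, AA, CBM) for direct count-matrix draws
DEFAULT_CATEGORY_MEDIANS: dict[str, float] = {
    "GH": 84, "GT": 77, "PL": 14, "CE": 63, "AA": 19, "CBM": 62,
}


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for the synthetic generator."""

    n_organisms: int | None = None  # None -> sum of taxonomy_spec members
    taxonomy_spec: tuple[tuple[str, str, int], ...] = DEFAULT_TAXONOMY
    cds_range: tuple[int, int] = (1500, 15000)
    pct_cazyme_by_family: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PCT_CAZYME)
    )
    genome_mb_by_family: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_GENOME_MB)
    )
    architecture_pool: tuple[tuple[tuple[str, ...], float], ...] = (
        DEFAULT_ARCHITECTURE_POOL
    )
    decoy_rates: tuple[float, float] = (0.4, 0.2)  # (overlap decoys/true hit, noise/true hit)
    true_coverage_range: tuple[float, float] = (0.70, 1.0)
    true_log10_ievalue_range: tuple[float, float] = (-60.0, -20.0)
    decoy_log10_penalty_range: tuple[float, float] = (3.0, 6.0)
    noise_coverage_range: tuple[float, float] = (0.05, 0.30)
    category_medians: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_MEDIANS)
    )
    category_dispersion: float = 0.20  # per-category lognormal sigma
    shared_dispersion: float = 0.35  # organism-level size-factor sigma
    seed: int = 0

    def __post_init__(self) -> None:
        if any(r < 0 for r in self.decoy_rates):
            raise ValueError("decoy rates must be non-negative")
        if not self.taxonomy_spec:
            raise ValueError("taxonomy_spec is empty")
        for tmpl, w in self.architecture_pool:
            if w < 0:
                raise ValueError("architecture weights must be non-negative")
            for fam in tmpl:
                parse_family_label(fam)  # raises on unknown families

    def organism_table(self) -> list[tuple[str, str]]:
        """(suborder, family) per organism, truncated/cycled to n_organisms."""
        rows = [
            (sub, fam)
            for sub, fam, n in self.taxonomy_spec
            for _ in range(n)
        ]
        if self.n_organisms is None:
            return rows
        if self.n_organisms <= len(rows):
            return rows[: self.n_organisms]
        reps = -(-self.n_organisms // len(rows))
        return (rows * reps)[: self.n_organisms]


def _hmm_length(family: FamilyLabel) -> int:
    """Deterministic pseudo-profile length per family (100-600 columns)."""
    return 100 + zlib.crc32(family.canonical.encode()) % 501


@dataclass
class OrganismTruth:
    """Planted ground truth for one organism."""

    tag: str
    architectures: list[tuple[str, tuple[str, ...]]]  # (protein_id, template)
    category_counts: dict[str, int]
    substrate_counts: dict[str, int]
    total_cds: int

    @property
    def cazyme_cds(self) -> int:
        return len(self.architectures)

    @property
    def pct_cazyme(self) -> float:
        return 100.0 * self.cazyme_cds / self.total_cds


@dataclass
class SyntheticDataset:
    """In-memory result of :func:`generate_dataset`."""

    metadata: pd.DataFrame
    hits_by_organism: dict[str, list[DomainHit]]
    truth: dict[str, OrganismTruth]

    def write(self, outdir: Union[str, Path]) -> Path:
        """Write metadata.tsv, domtblout/<tag>.domtblout and truth/*.tsv."""
        outdir = Path(outdir)
        (outdir / "domtblout").mkdir(parents=True, exist_ok=True)
        (outdir / "truth").mkdir(exist_ok=True)
        self.metadata.to_csv(outdir / "metadata.tsv", sep="\t", index=False)
        for tag, hits in self.hits_by_organism.items():
            write_domtblout(hits, outdir / "domtblout" / f"{tag}.domtblout")
        arch_rows = [
            {
                "tag": t.tag,
                "protein_id": pid,
                "architecture": "+".join(tmpl),
                "n_domains": len(tmpl),
            }
            for t in self.truth.values()
            for pid, tmpl in t.architectures
        ]
        pd.DataFrame(arch_rows).to_csv(
            outdir / "truth" / "architectures.tsv", sep="\t", index=False
        )
        cat_rows = [
            {"tag": t.tag, **t.category_counts} for t in self.truth.values()
        ]
        pd.DataFrame(cat_rows).to_csv(
            outdir / "truth" / "category_counts.tsv", sep="\t", index=False
        )
        sub_rows = [
            {"tag": t.tag, **t.substrate_counts} for t in self.truth.values()
        ]
        pd.DataFrame(sub_rows).to_csv(
            outdir / "truth" / "substrate_counts.tsv", sep="\t", index=False
        )
        prof_rows = [
            {
                "tag": t.tag,
                "cazyme_cds": t.cazyme_cds,
                "total_cds": t.total_cds,
                "pct_cazyme": t.pct_cazyme,
            }
            for t in self.truth.values()
        ]
        pd.DataFrame(prof_rows).to_csv(
            outdir / "truth" / "profile.tsv", sep="\t", index=False
        )
        return outdir


def _template_truth_counts(
    templates: Iterable[tuple[str, ...]], smap: SubstrateMap
) -> tuple[dict[str, int], dict[str, int]]:
    """Protein-level category and substrate counts straight from templates."""
    cat_counts = {c: 0 for c in ("GH", "GT", "PL", "CE", "AA", "CBM")}
    sub_counts = {s.value: 0 for s in Substrate}
    for tmpl in templates:
        labels = [parse_family_label(f) for f in tmpl]
        for cat in {lab.category.value for lab in labels}:
            cat_counts[cat] += 1
        reachable: set[str] = set()
        for lab in labels:
            reachable |= {s.value for s in smap.substrates_for(lab)}
        for s in reachable:
            sub_counts[s] += 1
    return cat_counts, sub_counts


def _plant_protein(
    rng: np.random.Generator,
    cfg: SimConfig,
    protein_id: str,
    tag: str,
    template: tuple[str, ...],
) -> tuple[list[DomainHit], list[DomainHit]]:
    """True hits realising one template, plus its overlap/noise decoys.

    Consecutive planted domains are separated by a gap larger than 60% of the
    longer flanking domain, so an overlap decoy (shifted by under half its
    source length) can never reach a neighbouring true domain.
    """
    cov_lo, cov_hi = cfg.true_coverage_range
    le_lo, le_hi = cfg.true_log10_ievalue_range
    true_hits: list[DomainHit] = []
    decoys: list[DomainHit] = []
    pos = int(rng.integers(1, 40))
    prev_len = 0
    for fam_s in template:
        fam = parse_family_label(fam_s)
        L = _hmm_length(fam)
        cov = float(rng.uniform(cov_lo, cov_hi))
        span = max(1, round(cov * L))
        hmm_from = int(rng.integers(1, L - span + 2))
        ali_len = span
        if prev_len:
            pos += int(np.ceil(0.6 * max(prev_len, ali_len))) + int(rng.integers(5, 30))
        ali_from = pos
        ali_to = ali_from + ali_len - 1
        ievalue = 10.0 ** float(rng.uniform(le_lo, le_hi))
        hit = DomainHit(
            protein_id=protein_id,
            organism_tag=tag,
            family=fam,
            hmm_length=L,
            hmm_from=hmm_from,
            hmm_to=hmm_from + span - 1,
            ali_from=ali_from,
            ali_to=ali_to,
            env_from=max(1, ali_from - int(rng.integers(0, 4))),
            env_to=ali_to + int(rng.integers(0, 4)),
            full_seq_evalue=ievalue / 10.0,
            dom_ievalue=ievalue,
            dom_score=float(np.round(rng.uniform(50.0, 500.0), 1)),
        )
        true_hits.append(hit)
        pos = ali_to + 1
        prev_len = ali_len
    overlap_rate, noise_rate = cfg.decoy_rates
    pen_lo, pen_hi = cfg.decoy_log10_penalty_range
    for src in true_hits:
        if rng.random() < overlap_rate:
            shift = int(rng.integers(0, max(1, src.ali_length // 2 - 1)))
            if rng.random() < 0.5:
                shift = -min(shift, src.ali_from - 1)
            fam = src.family if rng.random() < 0.5 else parse_family_label("GH1")
            L = _hmm_length(fam)
            cov = float(rng.uniform(max(cov_lo - 0.2, 0.36), cov_hi))
            span = max(1, round(cov * L))
            decoys.append(
                DomainHit(
                    protein_id=protein_id,
                    organism_tag=tag,
                    family=fam,
                    hmm_length=L,
                    hmm_from=1,
                    hmm_to=span,
                    ali_from=src.ali_from + shift,
                    ali_to=src.ali_to + shift,
                    env_from=max(1, src.ali_from + shift - 2),
                    env_to=src.ali_to + shift + 2,
                    full_seq_evalue=src.dom_ievalue,
                    dom_ievalue=src.dom_ievalue
                    * 10.0 ** float(rng.uniform(pen_lo, pen_hi)),
                    dom_score=float(np.round(rng.uniform(10.0, 50.0), 1)),
                )
            )
    n_noise = int(rng.poisson(noise_rate * len(true_hits)))
    nc_lo, nc_hi = cfg.noise_coverage_range
    for _ in range(n_noise):
        fam = parse_family_label("CBM2")
        L = _hmm_length(fam)
        cov = float(rng.uniform(nc_lo, nc_hi))
        span = max(1, round(cov * L))
        start = int(rng.integers(1, max(2, pos)))
        decoys.append(
            DomainHit(
                protein_id=protein_id,
                organism_tag=tag,
                family=fam,
                hmm_length=L,
                hmm_from=1,
                hmm_to=span,
                ali_from=start,
                ali_to=start + span - 1,
                env_from=start,
                env_to=start + span - 1,
                full_seq_evalue=1e-20,
                dom_ievalue=10.0 ** float(rng.uniform(-30.0, -16.0)),
                dom_score=float(np.round(rng.uniform(5.0, 30.0), 1)),
            )
        )
    return true_hits, decoys


def generate_dataset(
    cfg: SimConfig | None = None,
    outdir: Union[str, Path, None] = None,
    smap: SubstrateMap | None = None,
) -> SyntheticDataset:
    """Generate metadata, per-organism domain tables and ground truth.

    Deterministic under a fixed ``cfg.seed`` (byte-identical files).  When
    ``outdir`` is given the dataset is also written in the standard run
    layout (metadata.tsv, domtblout/<tag>.domtblout, truth/*.tsv).
    """
    cfg = cfg or SimConfig()
    smap = smap or default_substrate_map()
    rng = np.random.default_rng(cfg.seed)
    templates = [t for t, _ in cfg.architecture_pool]
    weights = np.array([w for _, w in cfg.architecture_pool], dtype=float)
    if weights.sum() <= 0:
        raise ValueError("architecture pool weights sum to zero")
    weights = weights / weights.sum()

    meta_rows = []
    hits_by_organism: dict[str, list[DomainHit]] = {}
    truth: dict[str, OrganismTruth] = {}
    for i, (suborder, family) in enumerate(cfg.organism_table(), start=1):
        tag = f"org{i:02d}"
        mb_lo, mb_hi = cfg.genome_mb_by_family.get(family, (8.0, 12.0))
        genome_bp = int(rng.uniform(mb_lo, mb_hi) * 1e6)
        total_cds = int(
            np.clip(
                round(genome_bp / 1150.0 * np.exp(rng.normal(0.0, 0.05))),
                *cfg.cds_range,
            )
        )
        mean, sd = cfg.pct_cazyme_by_family.get(family, (3.0, 0.4))
        pct = float(np.clip(rng.normal(mean, sd), 0.5, 8.0))
        n_caz = max(1, round(pct / 100.0 * total_cds))
        habitat = "marine" if suborder in MARINE_SUBORDERS else "soil"
        gc = float(np.round(rng.uniform(66.0, 75.0), 2))
        meta_rows.append(
            {
                "tag": tag,
                "name": f"{family[:-4]} synthetica {tag}",
                "suborder": suborder,
                "family": family,
                "genus": family[:-4],
                "habitat": habitat,
                "genome_size_bp": genome_bp,
                "gc_percent": gc,
                "total_cds": total_cds,
            }
        )
        choice = rng.choice(len(templates), size=n_caz, p=weights)
        org_hits: list[DomainHit] = []
        org_archs: list[tuple[str, tuple[str, ...]]] = []
        for j, k in enumerate(choice, start=1):
            pid = f"{tag}_p{j:05d}"
            tmpl = templates[int(k)]
            true_hits, decoys = _plant_protein(rng, cfg, pid, tag, tmpl)
            org_hits.extend(true_hits)
            org_hits.extend(decoys)
            org_archs.append((pid, tmpl))
        cat_counts, sub_counts = _template_truth_counts(
            (t for _, t in org_archs), smap
        )
        hits_by_organism[tag] = org_hits
        truth[tag] = OrganismTruth(
            tag=tag,
            architectures=org_archs,
            category_counts=cat_counts,
            substrate_counts=sub_counts,
            total_cds=total_cds,
        )
    dataset = SyntheticDataset(
        metadata=pd.DataFrame(meta_rows), hits_by_organism=hits_by_organism, truth=truth
    )
    if outdir is not None:
        dataset.write(outdir)
    return dataset


def generate_count_matrix(
    cfg: SimConfig | None = None, n_organisms: int | None = None
) -> pd.DataFrame:
    """Draw an organisms x 6 CAZyme-category count matrix.

    Counts are lognormal-mixed around the configured category medians
    (multiplicative organism-level size factor shared across categories plus
    per-category noise), so sample medians track ``cfg.category_medians``
    and a dominant shared axis emerges, as in real category count tables.
    Zero dispersion reproduces the configured medians exactly.
    """
    cfg = cfg or SimConfig()
    n = n_organisms if n_organisms is not None else len(cfg.organism_table())
    rng = np.random.default_rng(cfg.seed)
    cats = list(cfg.category_medians)
    medians = np.array([cfg.category_medians[c] for c in cats], dtype=float)
    shared = rng.normal(0.0, cfg.shared_dispersion, size=(n, 1))
    noise = rng.normal(0.0, cfg.category_dispersion, size=(n, len(cats)))
    counts = np.rint(medians * np.exp(shared + noise)).astype(int)
    return pd.DataFrame(
        counts, columns=cats, index=[f"org{i:02d}" for i in range(1, n + 1)]
    )
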