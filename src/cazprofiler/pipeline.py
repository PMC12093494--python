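"""End-to-end orchestration: domain tables in, comparative tables out.

Stages run in order — read, filter, architect, profile, statistics — each
writing tab-delimited tables into the output directory, plus a JSON run
manifest recording the configuration, package version and SHA-256 checksums
of all inputs and outputs, so a re-run on identical inputs is provably
identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import pandas as pd

from . import __version__
from .architecture import build_architectures, cooccurrence_table, pattern_frequency
from .domtblout import group_by_protein, read_domtblout
from .filtering import FilterConfig, filter_organism
from .profiles import (
    build_profile,
    family_count_matrix,
    profiles_to_frame,
    read_metadata,
)
from .stats import (
    category_matrix,
    group_summarize,
    ols_r2,
    pairwise_welch,
    pca_counts,
)
from .vocab import SubstrateMap, default_substrate_map, load_substrate_map

log = logging.getLogger("cazprofiler")


@dataclass
class RunConfig:
    """Paths, thresholds and flags for one pipeline run."""

    input_dir: Path  # directory of <tag>.domtblout files
    metadata_path: Path
    output_dir: Path
    substrate_map_path: Path | None = None
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    granularity: str = "subfamily"  # tally granularity for architectures
    instance_level_families: bool = False
    pca_scale: bool = False
    welch_on: str = "pct_cazyme"  # column tested between groups
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.input_dir = Path(self.input_dir)
        self.metadata_path = Path(self.metadata_path)
        self.output_dir = Path(self.output_dir)
        if self.substrate_map_path is not None:
            self.substrate_map_path = Path(self.substrate_map_path)
        for p, what in [
            (self.input_dir, "input directory"),
            (self.metadata_path, "metadata file"),
        ]:
            if not p.exists():
                raise FileNotFoundError(f"{what} does not exist: {p}")
        if self.substrate_map_path is not None and not self.substrate_map_path.exists():
            raise FileNotFoundError(
                f"substrate map does not exist: {self.substrate_map_path}"
            )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path, **kw) -> Path:
    df.to_csv(path, sep="\t", **kw)
    return path


def run_pipeline(cfg: RunConfig) -> Path:
    """Run all stages and return the output directory.

    Any stage failure aborts with the stage name and offending file; the
    manifest marks the run complete only after every stage succeeded.
    """
    logging.basicConfig(level=cfg.log_level, format="%(levelname)s %(message)s")
    out = cfg.output_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": {
            "input_dir": str(cfg.input_dir),
            "metadata_path": str(cfg.metadata_path),
            "substrate_map_path": (
                str(cfg.substrate_map_path) if cfg.substrate_map_path else None
            ),
            "filter": vars(cfg.filter_config).copy(),
            "granularity": cfg.granularity,
            "pca_scale": cfg.pca_scale,
            "welch_on": cfg.welch_on,
        },
        "inputs": {},
        "outputs": {},
        "stages": [],
        "complete": False,
    }

    def stage(name: str):
        t0 = time.perf_counter()
        log.info("stage %s ...", name)

        def done():
            manifest["stages"].append(
                {"name": name, "seconds": round(time.perf_counter() - t0, 3)}
            )

        return done

    # --- read ---------------------------------------------------------
    done = stage("read")
    files = sorted(cfg.input_dir.glob("*.domtblout"))
    if not files:
        raise FileNotFoundError(f"no .domtblout files in {cfg.input_dir}")
    metadata = read_metadata(cfg.metadata_path)
    manifest["inputs"][str(cfg.metadata_path)] = _sha256(cfg.metadata_path)
    smap: SubstrateMap
    if cfg.substrate_map_path is not None:
        smap = load_substrate_map(cfg.substrate_map_path)
        manifest["inputs"][str(cfg.substrate_map_path)] = _sha256(cfg.substrate_map_path)
    else:
        smap = default_substrate_map()
    raw = {}
    for f in files:
        try:
            raw[f.stem] = read_domtblout(f)
        except ValueError as exc:
            raise RuntimeError(f"stage read failed on {f}: {exc}") from exc
        manifest["inputs"][str(f)] = _sha256(f)
    done()

    # --- filter -------------------------------------------------------
    done = stage("filter")
    filtered = {
        tag: filter_organism(group_by_protein(hits), cfg.filter_config)
        for tag, hits in raw.items()
    }
    hit_rows = [
        {
            "tag": tag,
            "protein_id": pid,
            "family": h.family.canonical,
            "ali_from": h.ali_from,
            "ali_to": h.ali_to,
            "coverage": h.coverage,
            "i_evalue": h.dom_ievalue,
            "score": h.dom_score,
        }
        for tag, by_prot in sorted(filtered.items())
        for pid, hits in sorted(by_prot.items())
        for h in hits
    ]
    outputs = {}
    outputs["filtered_hits"] = _write(
        pd.DataFrame(hit_rows), out / "filtered_hits.tsv", index=False
    )
    done()

    # --- architect ----------------------------------------------------
    done = stage("architect")
    archs_by_org = {tag: build_architectures(by_prot) for tag, by_prot in filtered.items()}
    all_archs = [a for archs in archs_by_org.values() for a in archs]
    arch_rows = [
        {
            "protein_id": a.protein_id,
            "tag": a.organism_tag,
            "architecture": a.architecture_string,
            "pattern": a.pattern.value,
            "n_domains": a.n_domains,
        }
        for a in all_archs
    ]
    outputs["architectures"] = _write(
        pd.DataFrame(arch_rows), out / "architectures.tsv", index=False
    )
    freq = pattern_frequency(all_archs, granularity=cfg.granularity)
    freq_df = pd.DataFrame(
        [
            {"family": f, "alone": a, "multi_copy": m, "with_accessory": w}
            for f, (a, m, w) in freq.items()
        ]
    )
    outputs["pattern_frequency"] = _write(
        freq_df, out / "pattern_frequency.tsv", index=False
    )
    coocc_rows = []
    for fam in freq_df["family"] if not freq_df.empty else []:
        for partner, n in sorted(
            cooccurrence_table(all_archs, fam, granularity=cfg.granularity).items()
        ):
            coocc_rows.append({"family": fam, "partner": partner, "proteins": n})
    outputs["cooccurrence"] = _write(
        pd.DataFrame(coocc_rows, columns=["family", "partner", "proteins"]),
        out / "cooccurrence.tsv",
        index=False,
    )
    done()

    # --- profile ------------------------------------------------------
    done = stage("profile")
    profiles = []
    for _, row in metadata.iterrows():
        tag = str(row["tag"])
        profiles.append(build_profile(row, archs_by_org.get(tag, []), smap))
    pframe = profiles_to_frame(profiles)
    outputs["profiles"] = _write(pframe, out / "profiles.tsv", index=False)
    outputs["family_counts"] = _write(
        family_count_matrix(profiles), out / "family_counts.tsv", index_label="tag"
    )
    sub_cols = ["tag"] + [c for c in pframe.columns if c.startswith("n_") and
                          c[2:] not in {"GH", "GT", "PL", "CE", "AA", "CBM"}]
    outputs["substrate_counts"] = _write(
        pframe[sub_cols], out / "substrate_counts.tsv", index=False
    )
    done()

    # --- stats --------------------------------------------------------
    done = stage("stats")
    values = pframe.set_index("tag")[cfg.welch_on]
    summaries = []
    for level in ("suborder", "family", "habitat"):
        grouping = pframe.set_index("tag")[level].to_dict()
        summaries.extend(group_summarize(values, grouping, level=level))
    outputs["group_summaries"] = _write(
        pd.DataFrame([vars(s) for s in summaries]),
        out / "group_summaries.tsv",
        index=False,
    )
    welch_rows = []
    for level in ("suborder", "habitat"):
        grouping = pframe.set_index("tag")[level].to_dict()
        for r in pairwise_welch(values, grouping):
            welch_rows.append(
                {
                    "level": level,
                    "group_a": r.groups[0],
                    "group_b": r.groups[1],
                    "t": r.t_statistic,
                    "dof": r.dof,
                    "p_value": r.p_value,
                }
            )
    outputs["welch_tests"] = _write(
        pd.DataFrame(
            welch_rows, columns=["level", "group_a", "group_b", "t", "dof", "p_value"]
        ),
        out / "welch_tests.tsv",
        index=False,
    )
    total_counts = pframe[[f"n_{c}" for c in ("GH", "GT", "PL", "CE", "AA", "CBM")]].sum(axis=1)
    reg_rows = []
    fit = ols_r2(pframe["genome_size_bp"], pframe["total_cds"])
    reg_rows.append({"x": "genome_size_bp", "y": "total_cds", **vars(fit)})
    fit = ols_r2(pframe["genome_size_bp"], total_counts)
    reg_rows.append({"x": "genome_size_bp", "y": "cazyme_category_total", **vars(fit)})
    outputs["regression"] = _write(
        pd.DataFrame(reg_rows), out / "regression.tsv", index=False
    )
    pca = pca_counts(category_matrix(pframe), scale=cfg.pca_scale)
    outputs["pca_variance"] = _write(
        pd.DataFrame(
            {
                "component": [f"PC{i+1}" for i in range(len(pca.variance_fraction))],
                "variance_fraction": pca.variance_fraction,
            }
        ),
        out / "pca_variance.tsv",
        index=False,
    )
    outputs["pca_loadings"] = _write(
        pd.DataFrame(
            pca.loadings,
            columns=pca.columns,
            index=[f"PC{i+1}" for i in range(pca.loadings.shape[0])],
        ),
        out / "pca_loadings.tsv",
        index_label="component",
    )
    outputs["pca_scores"] = _write(
        pd.DataFrame(
            pca.scores,
            index=pframe["tag"],
            columns=[f"PC{i+1}" for i in range(pca.scores.shape[1])],
        ),
        out / "pca_scores.tsv",
        index_label="tag",
    )
    done()

    for name, path in outputs.items():
        manifest["outputs"][name] = {"path": str(path), "sha256": _sha256(path)}
    manifest["complete"] = True
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    log.info("pipeline complete: %s", out)
    return out
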