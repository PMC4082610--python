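"""End-to-end orchestration: coverage -> units -> BPKM -> pairs -> statistics.

Units are called per species from coverage merged over the three
conditions (so a transcript expressed only under stress is still present
in the unit set), then quantified per condition. Downstream stages follow
the working-set logic: classify against the ORF annotation, couple
sense-antisense pairs, keep pairs expressed in every sample of both
species whose sense ORF has a one-to-one homolog, and compute the
comparative statistics (correlation matrices, inverse-expression
classification, conservation scoring and enrichment).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import comparative, metagene, quantify
from .discovery import TranscriptUnit, assert_non_overlapping, call_transcripts, write_units
from .io_coverage import (
    GenomeAnnotation,
    ReadFragment,
    StrandedCoverage,
    build_coverage,
    load_alignments,
    load_annotation,
    read_bedgraph_pair,
    read_chrom_sizes,
)

logger = logging.getLogger(__name__)

SPECIES = ("Sc", "Sp")
CONDITIONS = ("ML", "ES", "HS")


@dataclass
class PipelineParams:
    """Stage parameters with the analysis defaults."""

    min_seed_depth: int = 5
    edge_ratio: float = 4.0
    min_length: int = 1
    fold_threshold: float = 1.5
    fold_mode: str = "both"
    stringent_cut: float = 0.8
    background_cut: float = 0.5
    min_bpkm: float = 0.0
    log_pseudocount: float = 0.0
    strand_dialect: str = "dutp"

    def validate(self) -> None:
        errors = []
        if self.min_seed_depth <= 0:
            errors.append("min_seed_depth must be positive")
        if self.edge_ratio <= 0:
            errors.append("edge_ratio must be positive")
        if self.min_length <= 0:
            errors.append("min_length must be positive")
        if self.fold_threshold < 1:
            errors.append("fold_threshold must be >= 1")
        if not 0 <= self.background_cut <= self.stringent_cut <= 1:
            errors.append("need 0 <= background_cut <= stringent_cut <= 1")
        if self.fold_mode not in ("both", "either"):
            errors.append(f"unknown fold_mode {self.fold_mode!r}")
        if errors:
            raise ValueError("; ".join(errors))


@dataclass
class SpeciesResult:
    units: list[TranscriptUnit]
    expression: pd.DataFrame  # unit x condition BPKM
    pairs: pd.DataFrame
    filtered_pairs: pd.DataFrame
    metagene: "metagene.MetageneProfile | None" = None


@dataclass
class PipelineResult:
    species: dict[str, SpeciesResult]
    joined: pd.DataFrame  # homolog-joined conservation records
    pair_expression: pd.DataFrame  # per joined pair, sense/anti BPKM x sample
    inverse_records: pd.DataFrame
    inverse_summary: pd.DataFrame
    correlations: dict[str, pd.DataFrame]  # "sense"/"antisense" 6x6
    enrichment: dict[str, dict]  # per condition
    report: dict


def _class_counts(units: Sequence[TranscriptUnit]) -> dict:
    counts = {"ORF-T": 0, "ncRNA": 0, "other": 0}
    for u in units:
        if u.unit_class in counts:
            counts[u.unit_class] += 1
    counts["total"] = len(units)
    return counts


def analyze(
    coverages: Mapping[tuple[str, str], StrandedCoverage],
    fragments: Mapping[tuple[str, str], Sequence[ReadFragment]],
    annotations: Mapping[str, GenomeAnnotation],
    homology: pd.DataFrame,
    params: PipelineParams | None = None,
    compute_metagene: bool = True,
) -> PipelineResult:
    """Run the full analysis from per-sample coverage/fragments.

    ``coverages`` and ``fragments`` are keyed by (species, condition) with
    species in {"Sc", "Sp"} and condition in {"ML", "ES", "HS"}.
    """
    params = params or PipelineParams()
    params.validate()
    missing = [
        (sp, c) for sp in SPECIES for c in CONDITIONS if (sp, c) not in coverages
    ]
    if missing:
        raise ValueError(f"manifest missing samples: {missing}")

    per_species: dict[str, SpeciesResult] = {}
    for sp in SPECIES:
        merged = coverages[(sp, "ML")]
        for cond in CONDITIONS[1:]:
            merged = merged.merged_with(coverages[(sp, cond)])
        all_frags = [f for cond in CONDITIONS for f in fragments[(sp, cond)]]
        units = call_transcripts(
            merged,
            all_frags,
            min_seed_depth=params.min_seed_depth,
            edge_ratio=params.edge_ratio,
            min_length=params.min_length,
            id_prefix=f"{sp}_TU",
        )
        assert_non_overlapping(units)
        units = quantify.classify_units(units, annotations[sp])
        expr = quantify.expression_table(
            units, {cond: coverages[(sp, cond)] for cond in CONDITIONS}
        )
        pairs = quantify.pair_sense_antisense(units)
        filtered = quantify.filter_expressed_all(
            expr, pairs, min_bpkm=params.min_bpkm
        )
        per_species[sp] = SpeciesResult(
            units=units, expression=expr, pairs=pairs, filtered_pairs=filtered
        )
        logger.info(
            "%s: %d units (%s), %d pairs, %d expressed-in-all",
            sp, len(units), _class_counts(units), len(pairs), len(filtered),
        )

    # --- homology join over expressed-in-all pairs -------------------------------
    orf_of_unit = {
        sp: {
            u.id: u.orf_id
            for u in per_species[sp].units
            if u.unit_class == "ORF-T" and u.orf_id
        }
        for sp in SPECIES
    }
    joined = comparative.join_homologs(
        per_species["Sc"].filtered_pairs,
        per_species["Sp"].filtered_pairs,
        homology,
        orf_of_unit["Sc"],
        orf_of_unit["Sp"],
    )
    # working set: antisense expressed in all samples of BOTH species
    working = joined[(joined["O_Sc"] > 0) & (joined["O_Sp"] > 0)].reset_index(
        drop=True
    )

    # --- per-pair expression across the six samples ------------------------------
    rows = []
    for r in working.itertuples():
        row = {"pair": r.sc_orf_id}
        ok = True
        for sp, unit_id, anti_id in (
            ("Sc", r.sc_unit_id, r.sc_antisense_id),
            ("Sp", r.sp_unit_id, r.sp_antisense_id),
        ):
            expr = per_species[sp].expression
            for cond in CONDITIONS:
                row[f"sense_{sp}_{cond}"] = float(expr.loc[unit_id, cond])
                row[f"anti_{sp}_{cond}"] = float(expr.loc[anti_id, cond])
        rows.append(row)
    pair_expr = (
        pd.DataFrame(rows).set_index("pair")
        if rows
        else pd.DataFrame(
            columns=[
                f"{kind}_{sp}_{cond}"
                for kind in ("sense", "anti")
                for sp in SPECIES
                for cond in CONDITIONS
            ]
        )
    )
    working = working.set_index("sc_orf_id", drop=False).loc[
        pair_expr.index if len(pair_expr) else []
    ].reset_index(drop=True) if len(pair_expr) else working

    # --- comparative statistics ---------------------------------------------------
    correlations = {}
    if len(pair_expr) >= 3:
        for kind, prefix in (("sense", "sense"), ("antisense", "anti")):
            cols = [
                f"{prefix}_{sp}_{cond}" for cond in CONDITIONS for sp in SPECIES
            ]
            mat = comparative.correlation_matrix(
                pair_expr, samples=cols,
                log_pseudocount=params.log_pseudocount,
            )
            mat.index = mat.columns = [
                f"{sp}-{cond}" for cond in CONDITIONS for sp in SPECIES
            ]
            correlations[kind] = mat

    if len(pair_expr):
        inverse_records = comparative.classify_inverse(
            pair_expr, fold_threshold=params.fold_threshold, mode=params.fold_mode
        )
        inv_summary = comparative.inverse_summary(inverse_records)
        flags = comparative.pair_inverse_flags(inverse_records)
    else:
        inverse_records = pd.DataFrame(
            columns=["pair", "species", "condition", "sense_fc", "antisense_fc",
                     "category", "significant"]
        )
        inv_summary = pd.DataFrame()
        flags = pd.DataFrame()

    enrichment = {}
    for cond in ("ES", "HS"):
        if not len(working):
            enrichment[cond] = {"error": "no pairs in working set"}
            continue
        try:
            res = comparative.conservation_enrichment(
                working.assign(S=working["S"]).rename(
                    columns={"sc_orf_id": "sc_orf_id"}
                ),
                flags,
                cond,
                stringent_cut=params.stringent_cut,
                background_cut=params.background_cut,
            )
            res["table"] = res["table"].tolist()
            enrichment[cond] = res
        except ValueError as exc:
            enrichment[cond] = {"error": str(exc)}

    # --- metagene over the working set's sense units (mid-log sample) -------------
    if compute_metagene:
        for sp in SPECIES:
            cov_ml = coverages[(sp, "ML")]
            expr = per_species[sp].expression
            unit_col = "sc_unit_id" if sp == "Sc" else "sp_unit_id"
            anti_col = "sc_antisense_id" if sp == "Sc" else "sp_antisense_id"
            units_by_id = {u.id: u for u in per_species[sp].units}
            profs = []
            for r in working.itertuples():
                u = units_by_id[getattr(r, unit_col)]
                if u.length < metagene.N_BODY_BINS:
                    continue
                anti_id = getattr(r, anti_col)
                norm = (expr.loc[u.id, "ML"] + expr.loc[anti_id, "ML"]) / 2
                if norm <= 0:
                    continue
                profs.append(
                    metagene.gene_profile(
                        cov_ml, u.chrom, u.strand, u.start, u.end, norm
                    )
                )
            if profs:
                per_species[sp].metagene = metagene.mean_profile(profs)

    # --- report -------------------------------------------------------------------
    shared_orf_ts = {
        h.sc_orf_id
        for h in homology.itertuples()
        if h.sc_orf_id in set(orf_of_unit["Sc"].values())
        and h.sp_orf_id in set(orf_of_unit["Sp"].values())
    }
    report = {
        "unit_counts": {sp: _class_counts(per_species[sp].units) for sp in SPECIES},
        "orf_ts_shared": len(shared_orf_ts),
        "pairs_per_species": {sp: int(len(per_species[sp].pairs)) for sp in SPECIES},
        "pairs_expressed_in_all": {
            sp: int(len(per_species[sp].filtered_pairs)) for sp in SPECIES
        },
        "working_set_size": int(len(working)),
        "correlations": {
            k: v.round(4).to_dict() for k, v in correlations.items()
        },
        "inverse_summary": {
            str(cat): {
                f"{sg}/{cg}": int(v)
                for (sg, cg), v in inv_summary.loc[cat].items()
            }
            for cat in inv_summary.index
        }
        if len(inv_summary)
        else {},
        "enrichment": enrichment,
        "params": vars(params),
    }
    return PipelineResult(
        species=per_species,
        joined=working,
        pair_expression=pair_expr,
        inverse_records=inverse_records,
        inverse_summary=inv_summary,
        correlations=correlations,
        enrichment=enrichment,
        report=report,
    )


# ---------------------------------------------------------------------------
# file-based entry point


REQUIRED_MANIFEST_KEYS = {"species", "condition"}
KNOWN_CONFIG_KEYS = {
    "samples", "annotations", "homology", "out_dir", "params", "seed",
    "chrom_sizes",
}


def validate_config(path: str | Path) -> dict:
    """Load and normalize a pipeline YAML config, filling parameter defaults.

    Schema violations are collected and reported together.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    errors = []
    unknown = set(raw) - KNOWN_CONFIG_KEYS
    if unknown:
        errors.append(f"unknown config keys: {sorted(unknown)}")
    samples = raw.get("samples", [])
    seen = set()
    for s in samples:
        key = (s.get("species"), s.get("condition"))
        if not REQUIRED_MANIFEST_KEYS <= set(s):
            errors.append(f"sample entry missing species/condition: {s}")
            continue
        seen.add(key)
    expected = {(sp, c) for sp in SPECIES for c in CONDITIONS}
    if samples and seen != expected:
        errors.append(
            f"manifest must contain exactly two species x three conditions; "
            f"missing {sorted(expected - seen)}, extra {sorted(seen - expected)}"
        )
    params = PipelineParams(**raw.get("params", {}))
    try:
        params.validate()
    except (ValueError, TypeError) as exc:
        errors.append(str(exc))
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    out = dict(raw)
    out["params"] = params
    return out


def run_pipeline(config_path: str | Path, out_dir: str | Path | None = None) -> PipelineResult:
    """File-based pipeline: read the config, load inputs, analyze, write outputs."""
    cfg = validate_config(config_path)
    base = Path(config_path).parent
    out = Path(out_dir or cfg.get("out_dir", "asconsv-out"))
    out.mkdir(parents=True, exist_ok=True)

    chrom_sizes = {
        sp: read_chrom_sizes(base / p) for sp, p in cfg["chrom_sizes"].items()
    }
    coverages: dict[tuple[str, str], StrandedCoverage] = {}
    fragments: dict[tuple[str, str], list[ReadFragment]] = {}
    for s in cfg["samples"]:
        key = (s["species"], s["condition"])
        sizes = chrom_sizes[s["species"]]
        if "alignments" in s:
            frags = load_alignments(
                base / s["alignments"], strand_dialect=cfg["params"].strand_dialect
            )
            coverages[key] = build_coverage(frags, sizes)
            fragments[key] = frags
        else:
            total = s.get("total_mapped_bases")
            coverages[key] = read_bedgraph_pair(
                base / s["plus_bedgraph"], base / s["minus_bedgraph"], sizes,
                total_mapped_bases=total,
            )
            fragments[key] = []
    annotations = {
        sp: load_annotation(base / p) for sp, p in cfg["annotations"].items()
    }
    homology = comparative.load_homology_map(base / cfg["homology"])

    result = analyze(
        coverages, fragments, annotations, homology, params=cfg["params"],
    )
    write_result(result, out)
    return result


def write_result(result: PipelineResult, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for sp, res in result.species.items():
        write_units(res.units, out / f"{sp}.units.gff3")
        res.expression.to_csv(out / f"{sp}.bpkm.tsv", sep="\t")
        res.pairs.to_csv(out / f"{sp}.pairs.tsv", sep="\t", index=False)
        res.filtered_pairs.to_csv(
            out / f"{sp}.pairs.expressed_in_all.tsv", sep="\t", index=False
        )
        if res.metagene is not None:
            metagene.profile_table(res.metagene).to_csv(
                out / f"{sp}.metagene.tsv", sep="\t", index=False
            )
    result.joined.to_csv(out / "conservation_records.tsv", sep="\t", index=False)
    result.pair_expression.to_csv(out / "pair_expression.tsv", sep="\t")
    result.inverse_records.to_csv(out / "inverse_records.tsv", sep="\t", index=False)
    if len(result.inverse_summary):
        result.inverse_summary.to_csv(out / "inverse_summary.tsv", sep="\t")
    for kind, mat in result.correlations.items():
        mat.to_csv(out / f"correlation_{kind}.tsv", sep="\t")
    with open(out / "report.json", "w") as fh:
        json.dump(result.report, fh, indent=2, sort_keys=True)
        fh.write("\n")
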