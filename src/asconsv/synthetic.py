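"""Ground-truthed simulation of the two-species, three-condition design.

The generator emulates the statistical structure the analysis assumes:

* two "species" (Sc, Sp) with one-to-one homologous gene sets laid out on
  a single chromosome with silent spacers wide enough to keep transcript
  units separable;
* log-normal expression with a shared cross-species latent term, scaled so
  sense expression correlates more strongly across species than antisense;
* antisense units anchored at the sense gene's 3' end with partial
  overlap, in a mix of cross-species-conserved overlap geometries
  (target conservation score S > 0.8) and divergent ones (S < 0.5);
* a planted subset of sense-antisense pairs with exact inverse expression
  (sense fold change 1/fold, antisense fold change fold) in early
  stationary phase and/or heat shock relative to mid-log, in both species;
* fragment counts Poisson in depth_scale x expression x (length/1kb),
  fragment positions uniform within the transcript, truncated-normal
  fragment lengths.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .io_coverage import (
    GenomeAnnotation,
    ReadFragment,
    StrandedCoverage,
    build_coverage,
    write_annotation_gff,
    write_bedgraph_pair,
)

SPECIES = ("Sc", "Sp")
CONDITIONS = ("ML", "ES", "HS")
CHROM = "chrI"


@dataclass
class SimulationConfig:
    """Knobs of the simulated study design (defaults = study conditions)."""

    seed: int = 0
    n_genes: int = 200
    chrom_length: int = 500_000
    gene_length_range: tuple[int, int] = (600, 2000)
    antisense_fraction: float = 0.6
    conserved_overlap_fraction: float = 0.6
    inverse_fraction_ES: float = 0.15
    inverse_fraction_HS: float = 0.25
    fold: float = 2.0
    fragment_length_mean: float = 250.0
    fragment_length_sd: float = 40.0
    depth_scale: float = 50.0
    sense_log_mean: float = 3.0
    antisense_log_mean: float = 1.5
    sense_log_sd: float = 1.0
    antisense_log_sd: float = 1.0
    cross_species_corr_sense: float = 0.9
    cross_species_corr_antisense: float = 0.4
    condition_log_sd: float = 0.25

    def validate(self) -> None:
        props = {
            "antisense_fraction": self.antisense_fraction,
            "conserved_overlap_fraction": self.conserved_overlap_fraction,
            "inverse_fraction_ES": self.inverse_fraction_ES,
            "inverse_fraction_HS": self.inverse_fraction_HS,
            "cross_species_corr_sense": self.cross_species_corr_sense,
            "cross_species_corr_antisense": self.cross_species_corr_antisense,
        }
        for name, v in props.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.fold < 1:
            raise ValueError("fold must be >= 1")
        if not self.cross_species_corr_sense > self.cross_species_corr_antisense:
            raise ValueError(
                "cross_species_corr_sense must exceed cross_species_corr_antisense"
            )
        if self.n_genes < 1 or self.chrom_length < 1:
            raise ValueError("n_genes and chrom_length must be positive")
        lo, hi = self.gene_length_range
        if not 200 <= lo <= hi:
            raise ValueError("gene_length_range must satisfy 200 <= lo <= hi")


@dataclass
class TruthSet:
    """Ground truth of one simulation.

    genes / antisense: interval tables per transcript (both species);
    expression: long table (transcript_id, species, condition, value);
    pairs: per homologous sense-antisense pair — overlap geometry per
    species, target conservation class and score, planted inverse labels;
    homology: the one-to-one ORF map.
    """

    genes: pd.DataFrame
    antisense: pd.DataFrame
    expression: pd.DataFrame
    pairs: pd.DataFrame
    homology: pd.DataFrame


@dataclass
class SimulationResult:
    config: SimulationConfig
    chrom_sizes: dict[str, dict[str, int]]  # species -> {chrom: length}
    fragments: dict[tuple[str, str], list[ReadFragment]]  # (species, cond)
    truth: TruthSet
    annotations: dict[str, GenomeAnnotation]  # species -> truth ORF annotation

    def coverage(self, species: str, condition: str) -> StrandedCoverage:
        return build_coverage(
            self.fragments[(species, condition)], self.chrom_sizes[species]
        )


def _corr_pair(rng, n, rho, sd, mean):
    """Two length-n vectors with correlation rho (shared-latent construction)."""
    z = rng.standard_normal(n)
    a = np.sqrt(rho) * z + np.sqrt(1 - rho) * rng.standard_normal(n)
    b = np.sqrt(rho) * z + np.sqrt(1 - rho) * rng.standard_normal(n)
    return mean + sd * a, mean + sd * b


def _layout(rng, cfg: SimulationConfig) -> pd.DataFrame:
    """Gene intervals for one species: alternating strands, wide spacers."""
    lo, hi = cfg.gene_length_range
    min_gap = int(2 * cfg.fragment_length_mean)
    margin = int(2 * cfg.fragment_length_mean)
    cursor = margin
    rows = []
    for i in range(cfg.n_genes):
        length = int(rng.integers(lo, hi + 1))
        strand = "+" if i % 2 == 0 else "-"
        rows.append((cursor, cursor + length, strand))
        gap = min_gap + int(rng.integers(0, int(cfg.fragment_length_mean) + 1))
        cursor += length + gap
    required = cursor + margin
    if required > cfg.chrom_length:
        raise ValueError(
            f"chrom_length {cfg.chrom_length} too small for {cfg.n_genes} genes "
            f"at the requested spacing; need at least {required}"
        )
    return pd.DataFrame(rows, columns=["start", "end", "strand"])


def simulate(config: SimulationConfig) -> SimulationResult:
    """Draw one complete two-species, three-condition data set."""
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_genes

    # --- gene layout, per species ------------------------------------------------
    genes = {}
    for sp in SPECIES:
        df = _layout(rng, cfg)
        df.insert(0, "id", [f"{sp}_G{i:04d}" for i in range(n)])
        df["chrom"] = CHROM
        df["species"] = sp
        genes[sp] = df
    homology = pd.DataFrame(
        {"sc_orf_id": genes["Sc"]["id"], "sp_orf_id": genes["Sp"]["id"]}
    )

    # --- antisense geometry -------------------------------------------------------
    n_anti = round(cfg.antisense_fraction * n)
    anti_idx = np.sort(rng.choice(n, size=n_anti, replace=False))
    n_cons = round(cfg.conserved_overlap_fraction * n_anti)
    cons_mask = np.zeros(n_anti, dtype=bool)
    cons_mask[rng.choice(n_anti, size=n_cons, replace=False)] = True

    anti_rows = []
    pair_rows = []
    for j, gi in enumerate(anti_idx):
        if cons_mask[j]:
            base = rng.uniform(0.35, 0.6)
            frac = {sp: base * rng.uniform(0.97, 1.03) for sp in SPECIES}
        else:
            big = rng.uniform(0.5, 0.7)
            small = big * rng.uniform(0.1, 0.3)
            if rng.random() < 0.5:
                frac = {"Sc": big, "Sp": small}
            else:
                frac = {"Sc": small, "Sp": big}
        geom = {}
        for sp in SPECIES:
            g = genes[sp].iloc[gi]
            length = g["end"] - g["start"]
            ov = max(1, round(frac[sp] * length))
            ext = int(rng.integers(50, 151))
            if g["strand"] == "+":  # 3' end is the right end; antisense on '-'
                a_start, a_end, a_strand = g["end"] - ov, g["end"] + ext, "-"
            else:  # 3' end is the left end; antisense on '+'
                a_start, a_end, a_strand = g["start"] - ext, g["start"] + ov, "+"
            aid = f"{sp}_A{gi:04d}"
            anti_rows.append(
                (aid, g["id"], CHROM, a_strand, a_start, a_end, ov, sp)
            )
            geom[sp] = (length, ov)
        (l_sc, o_sc), (l_sp, o_sp) = geom["Sc"], geom["Sp"]
        c_sc, c_sp = o_sc / l_sc, o_sp / l_sp
        s = min(c_sc, c_sp) / ((c_sc + c_sp) / 2)
        pair_rows.append(
            {
                "pair": genes["Sc"].iloc[gi]["id"],
                "gene_index": gi,
                "sc_gene": genes["Sc"].iloc[gi]["id"],
                "sp_gene": genes["Sp"].iloc[gi]["id"],
                "conserved_geometry": bool(cons_mask[j]),
                "L_Sc": l_sc, "O_Sc": o_sc, "L_Sp": l_sp, "O_Sp": o_sp,
                "target_S": s,
            }
        )
    antisense = pd.DataFrame(
        anti_rows,
        columns=["id", "sense_id", "chrom", "strand", "start", "end",
                 "overlap_len", "species"],
    )
    pair_columns = [
        "pair", "gene_index", "sc_gene", "sp_gene", "conserved_geometry",
        "L_Sc", "O_Sc", "L_Sp", "O_Sp", "target_S",
    ]
    pairs = pd.DataFrame(pair_rows, columns=pair_columns)

    # --- planted inverse labels ---------------------------------------------------
    n_pairs = len(pairs)
    for cond, frac_inv in (
        ("ES", cfg.inverse_fraction_ES),
        ("HS", cfg.inverse_fraction_HS),
    ):
        planted = np.zeros(n_pairs, dtype=bool)
        k = round(frac_inv * n_pairs)
        if k:
            planted[rng.choice(n_pairs, size=k, replace=False)] = True
        pairs[f"planted_{cond}"] = planted

    # --- expression truth ---------------------------------------------------------
    sense_log = dict(
        zip(
            SPECIES,
            _corr_pair(rng, n, cfg.cross_species_corr_sense,
                       cfg.sense_log_sd, cfg.sense_log_mean),
        )
    )
    anti_log_full = dict(
        zip(
            SPECIES,
            _corr_pair(rng, n, cfg.cross_species_corr_antisense,
                       cfg.antisense_log_sd, cfg.antisense_log_mean),
        )
    )
    log_fold = np.log2(cfg.fold)
    planted_by_cond = {
        cond: set(pairs.loc[pairs[f"planted_{cond}"], "gene_index"])
        for cond in ("ES", "HS")
    }
    expr_rows = []
    for sp in SPECIES:
        for gi in range(n):
            gid = genes[sp].iloc[gi]["id"]
            has_anti = gi in set(anti_idx)
            aid = f"{sp}_A{gi:04d}" if has_anti else None
            base_s = sense_log[sp][gi]
            base_a = anti_log_full[sp][gi]
            for cond in CONDITIONS:
                if cond == "ML":
                    ds = da = 0.0
                elif gi in planted_by_cond[cond]:
                    ds, da = -log_fold, log_fold
                else:
                    ds = rng.normal(0.0, cfg.condition_log_sd)
                    da = rng.normal(0.0, cfg.condition_log_sd)
                expr_rows.append((gid, sp, cond, float(2.0 ** (base_s + ds))))
                if has_anti:
                    expr_rows.append((aid, sp, cond, float(2.0 ** (base_a + da))))
    expression = pd.DataFrame(
        expr_rows, columns=["transcript_id", "species", "condition", "value"]
    )

    # --- fragments ----------------------------------------------------------------
    transcripts = {}  # transcript_id -> (species, strand, start, end)
    for sp in SPECIES:
        for r in genes[sp].itertuples():
            transcripts[r.id] = (sp, r.strand, r.start, r.end)
        for r in antisense[antisense["species"] == sp].itertuples():
            transcripts[r.id] = (sp, r.strand, r.start, r.end)

    expr_lookup = {
        (r.transcript_id, r.species, r.condition): r.value
        for r in expression.itertuples()
    }
    fragments: dict[tuple[str, str], list[ReadFragment]] = {}
    chrom_sizes = {sp: {CHROM: cfg.chrom_length} for sp in SPECIES}
    for sp in SPECIES:
        for cond in CONDITIONS:
            frags: list[ReadFragment] = []
            for tid, (tsp, strand, t_start, t_end) in transcripts.items():
                if tsp != sp:
                    continue
                expr = expr_lookup[(tid, sp, cond)]
                t_len = t_end - t_start
                lam = cfg.depth_scale * expr * (t_len / 1e3)
                n_frag = int(rng.poisson(lam))
                if n_frag == 0:
                    continue
                max_len = min(int(2 * cfg.fragment_length_mean), t_len)
                lens = rng.normal(cfg.fragment_length_mean,
                                  cfg.fragment_length_sd, n_frag)
                lens = np.clip(np.round(lens), 30, max_len).astype(int)
                starts = t_start + (
                    rng.random(n_frag) * (t_len - lens + 1)
                ).astype(int)
                for s0, ln in zip(starts, lens):
                    frags.append(ReadFragment(CHROM, int(s0), int(s0 + ln), strand))
            frags.sort(key=lambda f: (f.chrom, f.start, f.end, f.strand))
            fragments[(sp, cond)] = frags

    # --- truth annotation objects ---------------------------------------------------
    annotations = {}
    for sp in SPECIES:
        orfs = genes[sp][["id", "chrom", "strand", "start", "end"]].copy()
        orfs["status"] = "verified"
        annotations[sp] = GenomeAnnotation(orfs=orfs.reset_index(drop=True))

    truth = TruthSet(
        genes=pd.concat(genes.values(), ignore_index=True),
        antisense=antisense,
        expression=expression,
        pairs=pairs,
        homology=homology,
    )
    return SimulationResult(
        config=cfg,
        chrom_sizes=chrom_sizes,
        fragments=fragments,
        truth=truth,
        annotations=annotations,
    )


def truth_report(truth: TruthSet) -> pd.DataFrame:
    """Per-pair truth rows for test assertions (one row per pair).

    Includes the overlap geometry, target conservation class/score,
    planted inverse labels, and the true per-species fold changes
    (condition vs mid-log) of both pair members.
    """
    cols = [
        "pair", "sc_gene", "sp_gene", "conserved_geometry", "target_S",
        "planted_ES", "planted_HS",
    ]
    for sp in SPECIES:
        for cond in ("ES", "HS"):
            cols += [f"sense_fc_{sp}_{cond}", f"antisense_fc_{sp}_{cond}"]
    if not len(truth.pairs):
        return pd.DataFrame(columns=cols)
    expr = truth.expression.set_index(["transcript_id", "species", "condition"])[
        "value"
    ]
    rows = []
    for r in truth.pairs.itertuples():
        gi = r.gene_index
        row = {
            "pair": r.pair,
            "sc_gene": r.sc_gene,
            "sp_gene": r.sp_gene,
            "conserved_geometry": r.conserved_geometry,
            "target_S": r.target_S,
            "planted_ES": r.planted_ES,
            "planted_HS": r.planted_HS,
        }
        for sp in SPECIES:
            gid = f"{sp}_G{gi:04d}"
            aid = f"{sp}_A{gi:04d}"
            for cond in ("ES", "HS"):
                row[f"sense_fc_{sp}_{cond}"] = (
                    expr[(gid, sp, cond)] / expr[(gid, sp, "ML")]
                )
                row[f"antisense_fc_{sp}_{cond}"] = (
                    expr[(aid, sp, cond)] / expr[(aid, sp, "ML")]
                )
        rows.append(row)
    return pd.DataFrame(rows, columns=cols)


def write_outputs(result: SimulationResult, out_dir: str | Path) -> None:
    """Write bedGraph pairs per sample, truth tables, GFF3s, and the config."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for (sp, cond), frags in sorted(result.fragments.items()):
        cov = build_coverage(frags, result.chrom_sizes[sp])
        write_bedgraph_pair(
            cov,
            out / f"{sp}-{cond}.plus.bedgraph",
            out / f"{sp}-{cond}.minus.bedgraph",
        )
        with open(out / f"{sp}-{cond}.total_mapped_bases.txt", "w") as fh:
            fh.write(f"{cov.total_mapped_bases}\n")
    for sp, ann in sorted(result.annotations.items()):
        write_annotation_gff(ann, out / f"{sp}.genes.gff3")
        with open(out / f"{sp}.chrom.sizes", "w") as fh:
            for chrom, size in result.chrom_sizes[sp].items():
                fh.write(f"{chrom}\t{size}\n")
    result.truth.homology.to_csv(out / "homology.tsv", sep="\t", index=False)
    result.truth.pairs.to_csv(out / "truth_pairs.tsv", sep="\t", index=False)
    result.truth.antisense.to_csv(out / "truth_antisense.tsv", sep="\t", index=False)
    result.truth.expression.to_csv(out / "truth_expression.tsv", sep="\t", index=False)
    truth_report(result.truth).to_csv(out / "truth_report.tsv", sep="\t", index=False)
    cfg = asdict(result.config)
    cfg["gene_length_range"] = list(cfg["gene_length_range"])
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
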