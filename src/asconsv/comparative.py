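"""Cross-species and cross-condition sense/antisense statistics.

Covers homology joining of per-species sense-antisense pairs, expression
divergence (|log2 difference|), sample-by-sample correlation matrices,
the overlap-geometry conservation score

    S = min(C_Sc, C_Sp) / mean(C_Sc, C_Sp),    C_i = O_i / L_i,

where L_i is the sense transcript length and O_i the sense-antisense
overlap length in species i (S = 0 when both overlaps are absent; sequence
identity is deliberately not considered), inverse-expression
classification under a fold-change rule, and the enrichment tests
(Fisher's exact on stringent-vs-background conservation, a one-sided
two-sample proportion test, and the Wilcoxon rank-sum distribution-shift
test).
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

SPECIES = ("Sc", "Sp")
STRESS_CONDITIONS = ("ES", "HS")

#: inverse-expression categories, spelled out to avoid label ambiguity
REPRESSED_SENSE = "repressed-sense/induced-antisense"
INDUCED_SENSE = "induced-sense/repressed-antisense"
NO_CATEGORY = "none"


# ---------------------------------------------------------------------------
# homology join and conservation score


def load_homology_map(path) -> pd.DataFrame:
    """Two-column TSV (sc_orf_id, sp_orf_id); must be one-to-one."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = ["sc_orf_id", "sp_orf_id"]
    _check_one_to_one(df)
    return df


def _check_one_to_one(homologs: pd.DataFrame) -> None:
    for col in ("sc_orf_id", "sp_orf_id"):
        if homologs[col].duplicated().any():
            dups = homologs.loc[homologs[col].duplicated(), col].tolist()
            raise ValueError(f"homology map is not one-to-one: {col} duplicates {dups}")


def conservation_score(l_sc: float, o_sc: float, l_sp: float, o_sp: float) -> dict:
    """Overlap-geometry conservation of one homologous sense-antisense pair."""
    for l, o in ((l_sc, o_sc), (l_sp, o_sp)):
        if l <= 0:
            raise ValueError("sense length must be positive")
        if o < 0 or o > l:
            raise ValueError(f"overlap {o} outside [0, {l}]")
    c_sc, c_sp = o_sc / l_sc, o_sp / l_sp
    mean_c = (c_sc + c_sp) / 2.0
    s = min(c_sc, c_sp) / mean_c if mean_c > 0 else 0.0
    return {
        "L_Sc": l_sc, "O_Sc": o_sc, "L_Sp": l_sp, "O_Sp": o_sp,
        "C_Sc": c_sc, "C_Sp": c_sp, "S": s,
    }


def join_homologs(
    pairs_sc: pd.DataFrame,
    pairs_sp: pd.DataFrame,
    homologs: pd.DataFrame,
    orf_of_unit_sc: Mapping[str, str],
    orf_of_unit_sp: Mapping[str, str],
    orf_t_units_sc: Iterable[str] | None = None,
    orf_t_units_sp: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Join per-species primary pairs across the one-to-one homology map.

    A row is produced for every homologous ORF pair whose ORF-T unit exists
    in both species and which carries an antisense overlap in at least one
    species; an absent antisense contributes O = 0 for that species. Pair
    tables must carry the primary flag (only primary pairs are joined).
    Returns one row per homologous ORF pair with geometry columns and S.
    """
    _check_one_to_one(homologs)

    def per_species(pairs: pd.DataFrame, orf_of_unit: Mapping[str, str]) -> pd.DataFrame:
        prim = pairs[pairs["primary"]] if len(pairs) else pairs
        rows = {}
        for r in prim.itertuples():
            orf = orf_of_unit.get(r.orf_t_id)
            if orf is None:
                continue
            # keep the largest overlap per ORF if several ncRNAs pair to it
            if orf not in rows or r.overlap_len > rows[orf][1]:
                rows[orf] = (r.orf_t_id, r.overlap_len, r.sense_len, r.antisense_id)
        return pd.DataFrame(
            [(orf, *vals) for orf, vals in rows.items()],
            columns=["orf_id", "unit_id", "overlap_len", "sense_len", "antisense_id"],
        )

    sc = per_species(pairs_sc, orf_of_unit_sc)
    sp = per_species(pairs_sp, orf_of_unit_sp)
    sc_units = set(
        orf_of_unit_sc.values() if orf_t_units_sc is None else orf_t_units_sc
    )
    sp_units = set(
        orf_of_unit_sp.values() if orf_t_units_sp is None else orf_t_units_sp
    )
    sc_by_orf = {r.orf_id: r for r in sc.itertuples()} if len(sc) else {}
    sp_by_orf = {r.orf_id: r for r in sp.itertuples()} if len(sp) else {}
    # sense length fallback when the species has no pair: unknown here, must
    # come from the unit table; callers that need it pass lengths via pairs.
    out_rows = []
    for h in homologs.itertuples():
        if h.sc_orf_id not in sc_units or h.sp_orf_id not in sp_units:
            continue
        a, b = sc_by_orf.get(h.sc_orf_id), sp_by_orf.get(h.sp_orf_id)
        if a is None and b is None:
            continue  # antisense in neither species
        l_sc = a.sense_len if a is not None else (b.sense_len if b is not None else 0)
        l_sp = b.sense_len if b is not None else l_sc
        if a is not None:
            l_sc = a.sense_len
        o_sc = a.overlap_len if a is not None else 0
        o_sp = b.overlap_len if b is not None else 0
        rec = conservation_score(l_sc, o_sc, l_sp, o_sp)
        out_rows.append(
            {
                "sc_orf_id": h.sc_orf_id,
                "sp_orf_id": h.sp_orf_id,
                "sc_unit_id": a.unit_id if a is not None else None,
                "sp_unit_id": b.unit_id if b is not None else None,
                "sc_antisense_id": a.antisense_id if a is not None else None,
                "sp_antisense_id": b.antisense_id if b is not None else None,
                **rec,
            }
        )
    return pd.DataFrame(
        out_rows,
        columns=[
            "sc_orf_id", "sp_orf_id", "sc_unit_id", "sp_unit_id",
            "sc_antisense_id", "sp_antisense_id",
            "L_Sc", "O_Sc", "L_Sp", "O_Sp", "C_Sc", "C_Sp", "S",
        ],
    )


# ---------------------------------------------------------------------------
# expression divergence and correlation


def expression_variation(e_sc: float, e_sp: float) -> float:
    """Cross-species divergence: |log2 e_Sc - log2 e_Sp| (inputs positive)."""
    if e_sc <= 0 or e_sp <= 0:
        raise ValueError("expression values must be positive")
    return abs(math.log2(e_sc) - math.log2(e_sp))


def correlation_matrix(
    table: pd.DataFrame,
    samples: Sequence[str] | None = None,
    log_pseudocount: float = 0.0,
) -> pd.DataFrame:
    """Pearson correlation of log10 expression between every sample pair.

    Rows of ``table`` are transcripts of the filtered working set, columns
    are samples. With the default zero pseudocount all values must be
    positive (the expressed-in-all filter guarantees this).
    """
    if samples is None:
        samples = list(table.columns)
    sub = table.loc[:, list(samples)]
    if len(sub) < 3:
        raise ValueError("need at least 3 transcripts for a correlation matrix")
    if log_pseudocount == 0.0 and (sub <= 0).any().any():
        raise ValueError("non-positive expression with zero pseudocount")
    logged = np.log10(sub + log_pseudocount)
    mat = logged.corr(method="pearson")
    np.fill_diagonal(mat.values, 1.0)
    return mat


# ---------------------------------------------------------------------------
# inverse-expression classification


def classify_inverse(
    pair_expr: pd.DataFrame,
    fold_threshold: float = 1.5,
    mode: str = "both",
) -> pd.DataFrame:
    """Per (pair, species, stress condition) fold-change categories.

    ``pair_expr`` has one row per homologous pair and columns
    ``{sense|anti}_{Sc|Sp}_{ML|ES|HS}`` of BPKM values (ML must be
    positive). Fold changes are BPKM(condition)/BPKM(ML). The direction
    category needs only fc on opposite sides of 1; ``significant``
    additionally requires the 1.5-fold rule: with mode "both" (default)
    both members must pass (sense_fc <= 1/threshold AND antisense_fc >=
    threshold, or the mirror); mode "either" relaxes it to one member.
    """
    if mode not in ("both", "either"):
        raise ValueError(f"unknown threshold mode {mode!r}")
    if fold_threshold < 1:
        raise ValueError("fold_threshold must be >= 1")
    rows = []
    for r in pair_expr.itertuples():
        for sp in SPECIES:
            ml_s = getattr(r, f"sense_{sp}_ML")
            ml_a = getattr(r, f"anti_{sp}_ML")
            if ml_s <= 0 or ml_a <= 0:
                raise ValueError("ML expression must be positive (filter first)")
            for cond in STRESS_CONDITIONS:
                fc_s = getattr(r, f"sense_{sp}_{cond}") / ml_s
                fc_a = getattr(r, f"anti_{sp}_{cond}") / ml_a
                if fc_s < 1 and fc_a > 1:
                    cat = REPRESSED_SENSE
                    hits = (fc_s <= 1 / fold_threshold, fc_a >= fold_threshold)
                elif fc_s > 1 and fc_a < 1:
                    cat = INDUCED_SENSE
                    hits = (fc_s >= fold_threshold, fc_a <= 1 / fold_threshold)
                else:
                    cat, hits = NO_CATEGORY, (False, False)
                if cat == NO_CATEGORY:
                    sig = False
                elif mode == "both":
                    sig = all(hits)
                else:
                    sig = any(hits)
                rows.append((r.Index, sp, cond, fc_s, fc_a, cat, sig))
    return pd.DataFrame(
        rows,
        columns=[
            "pair", "species", "condition", "sense_fc", "antisense_fc",
            "category", "significant",
        ],
    )


def inverse_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Tally significant inverse pairs by species exclusivity and condition.

    Rows: the two direction categories. Columns: a MultiIndex of
    (Sc-only | Sp-only | both-species) x (ES-only | HS-only | both-conditions),
    plus per-species-group totals — the accounting behind condition-specific
    inverse-pair tables.
    """
    sig = records[records["significant"]]
    cats = (REPRESSED_SENSE, INDUCED_SENSE)
    species_groups = ("Sc-only", "Sp-only", "both-species")
    cond_groups = ("ES-only", "HS-only", "both-conditions")
    out = {}
    for cat in cats:
        sub = sig[sig["category"] == cat]
        # pair -> set of (species, condition) hits for this category
        hits: dict = {}
        for r in sub.itertuples():
            hits.setdefault(r.pair, set()).add((r.species, r.condition))
        counts = {(sg, cg): 0 for sg in species_groups for cg in cond_groups}
        totals = {sg: 0 for sg in species_groups}
        for pair, hs in hits.items():
            sp_set = {s for s, _ in hs}
            if sp_set == {"Sc"}:
                sg = "Sc-only"
                conds = {c for s, c in hs}
            elif sp_set == {"Sp"}:
                sg = "Sp-only"
                conds = {c for s, c in hs}
            else:
                sg = "both-species"
                # conserved in a condition = significant in both species there
                conds = {
                    c
                    for c in STRESS_CONDITIONS
                    if ("Sc", c) in hs and ("Sp", c) in hs
                }
                if not conds:  # both species hit, but in different conditions
                    continue
            if conds == {"ES"}:
                cg = "ES-only"
            elif conds == {"HS"}:
                cg = "HS-only"
            else:
                cg = "both-conditions"
            counts[(sg, cg)] += 1
            totals[sg] += 1
        out[cat] = {**counts, **{(sg, "total"): t for sg, t in totals.items()}}
    cols = pd.MultiIndex.from_tuples(
        [(sg, cg) for sg in species_groups for cg in (*cond_groups, "total")]
    )
    return pd.DataFrame(
        [[out[cat][(sg, cg)] for sg, cg in cols] for cat in cats],
        index=cats,
        columns=cols,
    )


def pair_inverse_flags(records: pd.DataFrame) -> pd.DataFrame:
    """Per-pair per-condition flags: significant inverse in Sc / Sp / both."""
    sig = records[records["significant"]]
    idx = sorted(records["pair"].unique())
    out = pd.DataFrame(index=idx)
    for cond in STRESS_CONDITIONS:
        for sp in SPECIES:
            hits = set(
                sig[(sig["condition"] == cond) & (sig["species"] == sp)]["pair"]
            )
            out[f"inverse_{sp}_{cond}"] = [p in hits for p in idx]
        out[f"inverse_both_{cond}"] = (
            out[f"inverse_Sc_{cond}"] & out[f"inverse_Sp_{cond}"]
        )
        out[f"inverse_any_{cond}"] = (
            out[f"inverse_Sc_{cond}"] | out[f"inverse_Sp_{cond}"]
        )
    return out


# ---------------------------------------------------------------------------
# enrichment and shift tests


def fisher_from_counts(table: Sequence[Sequence[int]], alternative: str = "two-sided"):
    """Fisher's exact test on an explicit 2x2 count table."""
    arr = np.asarray(table, dtype=int)
    if arr.shape != (2, 2) or (arr < 0).any():
        raise ValueError("need a 2x2 table of non-negative counts")
    if (arr.sum(axis=1) == 0).any() or (arr.sum(axis=0) == 0).any():
        raise ValueError("contingency table has an empty margin")
    odds, p = stats.fisher_exact(arr, alternative=alternative)
    return {"table": arr, "odds_ratio": float(odds), "p_value": float(p)}


def conservation_enrichment(
    records: pd.DataFrame,
    flags: pd.DataFrame,
    condition: str,
    stringent_cut: float = 0.8,
    background_cut: float = 0.5,
    alternative: str = "two-sided",
) -> dict:
    """Stringent-vs-background enrichment of conserved inverse expression.

    Rows of the 2x2 table: pairs with conservation score S >
    ``stringent_cut`` vs pairs with S < ``background_cut``. Columns, among
    pairs showing significant inverse expression in ``condition`` in at
    least one species: inverse in BOTH species ("conserved") vs in exactly
    one ("not conserved"). Returns the table and the Fisher exact p-value.
    """
    if condition not in STRESS_CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    s = records["S"].to_numpy()
    idx = records["sc_orf_id"] if "sc_orf_id" in records else records.index
    both = flags[f"inverse_both_{condition}"].reindex(idx).to_numpy()
    any_ = flags[f"inverse_any_{condition}"].reindex(idx).to_numpy()
    one_only = any_ & ~both
    stringent = s > stringent_cut
    background = s < background_cut
    table = [
        [int((stringent & both).sum()), int((stringent & one_only).sum())],
        [int((background & both).sum()), int((background & one_only).sum())],
    ]
    res = fisher_from_counts(table, alternative=alternative)
    res["condition"] = condition
    return res


def proportion_test(k1: int, n1: int, k2: int, n2: int) -> float:
    """One-sided two-sample proportion test (p1 > p2 alternative).

    Normal approximation with pooled variance and continuity correction,
    matching the classical two-sample proportion z-test.
    """
    if n1 <= 0 or n2 <= 0 or not (0 <= k1 <= n1) or not (0 <= k2 <= n2):
        raise ValueError("need 0 <= k <= n with n > 0")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return 1.0 if p1 <= p2 else 0.0
    se = math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    cc = 0.5 * (1 / n1 + 1 / n2)
    diff = p1 - p2
    cc = min(cc, abs(diff)) if diff != 0 else 0.0
    z = (diff - math.copysign(cc, diff)) / se
    return float(stats.norm.sf(z))


def distribution_shift_test(
    bpkm_condition: Sequence[float], bpkm_ml: Sequence[float]
) -> float:
    """One-sided Wilcoxon rank-sum: is the condition sample right-shifted?

    Applied to log BPKM (the log is rank-preserving, so ranks are computed
    on the raw positive values). Exact for small samples without ties.
    """
    a = np.asarray(bpkm_condition, dtype=float)
    b = np.asarray(bpkm_ml, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    if len(np.unique(np.concatenate([a, b]))) == 1:
        raise ValueError("degenerate all-tied input")
    res = stats.mannwhitneyu(a, b, alternative="greater", method="auto")
    return float(res.pvalue)
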