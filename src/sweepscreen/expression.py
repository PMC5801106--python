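"""Staged FPKM fold-change screen and term-set enrichment.

The screen compares mean FPKM of the high-anthocyanin accessions against the
non-anthocyanin controls at each of three post-heading time points. A time
point "passes" for a transcript when the high/none ratio reaches the fold
threshold (default 2) in a consistent direction; the staged screen then keeps
transcripts passing at least one (`any`), at least two (`at_least_k`), or all
(`all`) time points. Regulation is `up` when every time point is at or above
the threshold, `down` when every one is at or below its reciprocal.

Enrichment of a selection against a gene -> term membership table uses the
one-sided (upper-tail) Fisher/hypergeometric test, with a permutation FDR:
selection labels are shuffled over the universe (default 100 randomizations)
and each term's FDR is the mean number of null p-values at or below its
observed p, divided by the observed number of terms reaching that p.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GROUP_HIGH, GROUP_NONE

STAGES = ("any", "at_least_k", "all")


@dataclass
class ScreenConfig:
    fold_threshold: float = 2.0
    min_timepoints_stage2: int = 2
    n_timepoints: int = 3
    pseudocount: float = 0.01
    strict_direction: bool = True
    group_agg: str = "mean"  # or "median"
    enrichment_alpha: float = 0.05
    n_randomizations: int = 100
    fdr_alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.fold_threshold <= 1:
            raise ValueError("fold_threshold must exceed 1")
        if not 1 <= self.min_timepoints_stage2 <= self.n_timepoints:
            raise ValueError("min_timepoints_stage2 must be in [1, n_timepoints]")
        if self.group_agg not in ("mean", "median"):
            raise ValueError("group_agg must be 'mean' or 'median'")


def fold_change(fpkm_high: float, fpkm_none: float, pseudocount: float = 0.0) -> float:
    """Expression ratio (high + c) / (none + c); NaN when both are zero with c = 0."""
    if fpkm_high < 0 or fpkm_none < 0 or pseudocount < 0:
        raise ValueError("FPKM values and pseudocount must be non-negative")
    num = fpkm_high + pseudocount
    den = fpkm_none + pseudocount
    if den == 0:
        return float("nan") if num == 0 else float("inf")
    return num / den


def summarize_groups(fpkm: pd.DataFrame, groups: dict[str, str],
                     cfg: ScreenConfig) -> pd.DataFrame:
    """Collapse the long FPKM table to per-transcript, per-time-point group means.

    ``fpkm`` needs columns (transcript_id, sample_id, timepoint, fpkm). Output
    has one row per transcript with columns ``high_t{n}``, ``none_t{n}`` and
    ``ratio_t{n}`` for each time point, plus the geometric-mean ratio.
    Transcripts missing any (group, timepoint) cell are excluded and listed in
    the frame's ``attrs["excluded"]``.
    """
    required = {"transcript_id", "sample_id", "timepoint", "fpkm"}
    missing = required - set(fpkm.columns)
    if missing:
        raise ValueError(f"FPKM table missing columns: {sorted(missing)}")
    unknown = set(fpkm["sample_id"]) - set(groups)
    if unknown:
        raise ValueError(f"samples without a group assignment: {sorted(unknown)}")

    df = fpkm.copy()
    df["group"] = df["sample_id"].map(groups)
    agg = df.groupby(["transcript_id", "group", "timepoint"])["fpkm"].agg(cfg.group_agg)
    wide = agg.unstack(["group", "timepoint"])

    timepoints = sorted(df["timepoint"].unique())
    if len(timepoints) != cfg.n_timepoints:
        raise ValueError(
            f"expected {cfg.n_timepoints} time points, found {len(timepoints)}: {timepoints}")
    needed = [(g, t) for g in (GROUP_HIGH, GROUP_NONE) for t in timepoints]
    complete = wide[needed].notna().all(axis=1)
    excluded = sorted(wide.index[~complete])
    wide = wide[complete]

    out = pd.DataFrame(index=wide.index)
    for t in timepoints:
        out[f"high_t{t}"] = wide[(GROUP_HIGH, t)]
        out[f"none_t{t}"] = wide[(GROUP_NONE, t)]
        out[f"ratio_t{t}"] = (wide[(GROUP_HIGH, t)] + cfg.pseudocount) \
            / (wide[(GROUP_NONE, t)] + cfg.pseudocount)
    ratio_cols = [f"ratio_t{t}" for t in timepoints]
    out["ratio_geomean"] = np.exp(np.log(out[ratio_cols]).mean(axis=1))
    out = out.reset_index()
    out.attrs["excluded"] = excluded
    out.attrs["timepoints"] = timepoints
    return out


def _ratio_matrix(records: pd.DataFrame) -> np.ndarray:
    cols = [c for c in records.columns if c.startswith("ratio_t")]
    return records[cols].to_numpy(dtype=float)


def _pass_counts(ratios: np.ndarray, cfg: ScreenConfig) -> tuple[np.ndarray, np.ndarray]:
    up = ratios >= cfg.fold_threshold
    down = ratios <= 1.0 / cfg.fold_threshold
    return up.sum(axis=1), down.sum(axis=1)


def screen_stage(records: pd.DataFrame, stage: str, cfg: ScreenConfig) -> pd.DataFrame:
    """Subset the ratio table to transcripts passing the given stage.

    Under the default strict direction policy only time points moving the same
    way count, so a transcript twofold up at two time points and twofold down
    at the third passes `at_least_k` but never `all`.
    """
    if stage not in STAGES:
        raise ValueError(f"stage must be one of {STAGES}, got {stage!r}")
    ratios = _ratio_matrix(records)
    if ratios.shape[1] != cfg.n_timepoints:
        raise ValueError("records do not carry one ratio per configured time point")
    n_up, n_down = _pass_counts(ratios, cfg)
    if cfg.strict_direction:
        effective = np.maximum(n_up, n_down)
    else:
        effective = n_up + n_down
    k_needed = {"any": 1, "at_least_k": cfg.min_timepoints_stage2, "all": cfg.n_timepoints}[stage]
    return records[effective >= k_needed]


def classify_regulation(records: pd.DataFrame, cfg: ScreenConfig) -> pd.Series:
    """Per-transcript regulation call: up / down / none.

    `up` requires every time point's ratio at or above the fold threshold,
    `down` every one at or below its reciprocal; anything else is `none`.
    """
    ratios = _ratio_matrix(records)
    n_up, n_down = _pass_counts(ratios, cfg)
    T = ratios.shape[1]
    calls = np.where(n_up == T, "up", np.where(n_down == T, "down", "none"))
    return pd.Series(calls, index=records.index, name="regulation")


def fisher_enrichment(k: int, n_selected: int, m_in_term: int, n_universe: int) -> float:
    """One-sided Fisher's exact p-value: P[X >= k overlaps] under hypergeometric.

    ``k`` selected genes fall in a term of ``m_in_term`` genes, out of a
    selection of ``n_selected`` from a universe of ``n_universe``.
    """
    if not (0 <= k <= min(n_selected, m_in_term)):
        raise ValueError(f"inconsistent table: k={k}, n={n_selected}, m={m_in_term}")
    if max(n_selected, m_in_term) > n_universe:
        raise ValueError("margins exceed the universe size")
    if k < max(0, n_selected + m_in_term - n_universe):
        raise ValueError("k below the minimum possible overlap")
    return float(stats.hypergeom.sf(k - 1, n_universe, m_in_term, n_selected))


def _term_pvalues(member: np.ndarray, selected: np.ndarray) -> np.ndarray:
    """Upper-tail hypergeometric p per term; vectorised over the term axis.

    ``member`` is a boolean (n_terms, N) matrix, ``selected`` a boolean (N,)
    vector over the universe.
    """
    N = member.shape[1]
    n_sel = int(selected.sum())
    m = member.sum(axis=1)
    k = member.astype(np.int64) @ selected.astype(np.int64)
    return stats.hypergeom.sf(k - 1, N, m, n_sel)


def permutation_fdr(observed_p: pd.Series, selected_ids: set[str],
                    term_table: pd.DataFrame, universe: list[str],
                    n_randomizations: int = 100, seed: int = 0) -> pd.Series:
    """Permutation FDR for per-term enrichment p-values.

    For each randomization the selection labels are shuffled over the
    universe and all term p-values recomputed; FDR(term) is the mean count of
    null p-values <= p_obs(term) divided by the observed count of terms with
    p <= p_obs(term), clipped to [0, 1]. Deterministic given ``seed``.
    """
    if len(term_table) == 0:
        raise ValueError("empty term table")
    if n_randomizations < 1:
        raise ValueError("need at least one randomization")
    rng = np.random.default_rng(seed)
    terms = list(observed_p.index)
    uni_index = {g: i for i, g in enumerate(universe)}
    member = np.zeros((len(terms), len(universe)), dtype=bool)
    term_pos = {t: i for i, t in enumerate(terms)}
    for g, t in term_table[["gene_id", "term_id"]].itertuples(index=False):
        if t in term_pos and g in uni_index:
            member[term_pos[t], uni_index[g]] = True

    selected = np.zeros(len(universe), dtype=bool)
    for g in selected_ids:
        if g in uni_index:
            selected[uni_index[g]] = True

    obs = observed_p.to_numpy(dtype=float)
    null_leq = np.zeros(len(terms))
    for _ in range(n_randomizations):
        perm = rng.permutation(selected)
        null_p = _term_pvalues(member, perm)
        null_leq += (null_p[None, :] <= obs[:, None]).sum(axis=1)
    mean_null = null_leq / n_randomizations
    obs_count = (obs[None, :] <= obs[:, None]).sum(axis=1)
    fdr = np.clip(mean_null / np.maximum(obs_count, 1), 0.0, 1.0)
    return pd.Series(fdr, index=observed_p.index, name="fdr")


def enrich_terms(selected_ids: set[str], term_table: pd.DataFrame,
                 universe: list[str], cfg: ScreenConfig, seed: int = 0) -> pd.DataFrame:
    """Full per-term enrichment report: k, n, m, N, one-sided p, permutation FDR."""
    if len(term_table) == 0:
        raise ValueError("empty term table")
    uni = set(universe)
    sel = selected_ids & uni
    rows = []
    for term, sub in term_table.groupby("term_id", sort=True):
        members = set(sub["gene_id"]) & uni
        k = len(members & sel)
        rows.append((term, k, len(sel), len(members), len(uni),
                     fisher_enrichment(k, len(sel), len(members), len(uni))))
    report = pd.DataFrame(rows, columns=["term_id", "k", "n", "m", "N", "p"])
    report = report.set_index("term_id")
    report["fdr"] = permutation_fdr(report["p"], sel, term_table, list(universe),
                                    n_randomizations=cfg.n_randomizations, seed=seed)
    report["significant"] = (report["p"] <= cfg.enrichment_alpha) \
        & (report["fdr"] <= cfg.fdr_alpha)
    return report.reset_index()


def run_screen(fpkm: pd.DataFrame, groups: dict[str, str], cfg: ScreenConfig
               ) -> dict[str, pd.DataFrame]:
    """Run the staged screen and return per-stage tables plus the final report.

    The final report carries per-time-point ratios, their geometric mean and
    the regulation call for transcripts differentially expressed at all time
    points (the Table-3-shaped output of the screen).
    """
    records = summarize_groups(fpkm, groups, cfg)
    stage_any = screen_stage(records, "any", cfg)
    stage_k = screen_stage(stage_any, "at_least_k", cfg)
    stage_all = screen_stage(stage_k, "all", cfg)
    final = stage_all.copy()
    final["regulation"] = classify_regulation(stage_all, cfg)
    return {
        "records": records,
        "any": stage_any,
        "at_least_k": stage_k,
        "all": stage_all,
        "final": final,
    }
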