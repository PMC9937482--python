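"""Full-study orchestration: detection over all trials, condition pairings,
per-condition cross-recurrence aggregation, memory-performance tables and the
end-to-end pipeline.

The four scanpath-similarity conditions cross participant and image identity:

* Sp-Si - each 'old' recognition trial vs the same participant's encoding of
  the same scene;
* Sp-Di - each 'new' recognition trial vs the same participant's encoding of
  a randomly chosen dropped (encoded but not re-shown) scene;
* Dp-Si / Dp-Di - as above, with the encoding side taken from a randomly
  chosen *other* participant.

Memory tables report the standard movement measures by Hit/Miss (old scenes)
and Correct Rejection/False Alarm (new scenes), with exact Mann-Whitney U
contrasts; inference beyond those direction-preserving contrasts (mixed
models, odds ratios) is deliberately out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import cra, fixation, preprocess, spatial
from .synth import StudyConfig, StudyData, simulate_study

__all__ = [
    "detect_study",
    "fixation_sequences",
    "build_pairings",
    "run_condition_cra",
    "rm_anova_2x2",
    "exact_u_test",
    "memory_table",
    "scene_heatmaps",
    "run_pipeline",
    "StudyReport",
]

CONDITIONS = ["Sp-Si", "Sp-Di", "Dp-Si", "Dp-Di"]

FIXTABLE_COLUMNS = ["participant", "scene", "phase", "fix_index", "start_ms",
                    "end_ms", "dur_ms", "eye_lon", "eye_lat", "head_lon",
                    "head_lat"]


def detect_study(study: StudyData, max_dispersion=3.0, min_duration=80.0):
    """Preprocess and run fixation detection on every trial.

    Returns
    -------
    (fix_table, measures_table) : fixation-level and trial-level DataFrames.
    """
    fix_rows = []
    meas_rows = []
    for raw in study.trials:
        gaze = preprocess.build_gaze_series(raw)
        fx = fixation.detect_fixations_idt(
            gaze["t"].to_numpy(), gaze["eye_lon"].to_numpy(),
            gaze["eye_lat"].to_numpy(), max_dispersion, min_duration)
        hf = fixation.head_fixations(fx, gaze) if len(fx) else \
            pd.DataFrame(columns=["index", "head_lon", "head_lat"])
        m = fixation.trial_measures(fx, hf)
        meas_rows.append({
            "participant": raw.participant_id, "scene": raw.scene_id,
            "phase": raw.phase, "n_fixations": m.n_fixations,
            "mean_fixation_duration": m.mean_fixation_duration,
            "exploration_eye": m.exploration_eye,
            "exploration_head": m.exploration_head,
        })
        if len(fx):
            merged = fx.merge(hf, on="index")
            for r in merged.to_dict("records"):
                fix_rows.append({
                    "participant": raw.participant_id, "scene": raw.scene_id,
                    "phase": raw.phase, "fix_index": r["index"],
                    "start_ms": r["start_ms"], "end_ms": r["end_ms"],
                    "dur_ms": r["dur_ms"], "eye_lon": r["lon"],
                    "eye_lat": r["lat"], "head_lon": r["head_lon"],
                    "head_lat": r["head_lat"],
                })
    fix_table = pd.DataFrame(fix_rows, columns=FIXTABLE_COLUMNS)
    return fix_table, pd.DataFrame(meas_rows)


def fixation_sequences(fix_table: pd.DataFrame) -> dict:
    """(participant, scene, 'enc'|'rec') -> {'eye': (lon, lat), 'head': ...}."""
    seqs = {}
    for (p, s, ph), grp in fix_table.groupby(["participant", "scene", "phase"]):
        kind = "enc" if ph == "encoding" else "rec"
        grp = grp.sort_values("fix_index")
        seqs[(p, s, kind)] = {
            "eye": (grp["eye_lon"].to_numpy(), grp["eye_lat"].to_numpy()),
            "head": (grp["head_lon"].to_numpy(), grp["head_lat"].to_numpy()),
        }
    return seqs


def build_pairings(trial_table: pd.DataFrame, seed=0) -> dict:
    """Seeded pairings for the four conditions.

    Dropped-scene draws are without replacement within participant; the
    different-participant conditions never pair a participant with themselves.
    """
    rng = np.random.default_rng(seed)
    participants = sorted(trial_table["participant"].unique())
    old_trials = trial_table[trial_table["phase"] == "recognition_old"]
    new_trials = trial_table[trial_table["phase"] == "recognition_new"]
    d_set = sorted(trial_table.loc[
        (trial_table["phase"] == "encoding")
        & (trial_table["old_new"] == "dropped"), "scene"].unique())

    def other(p):
        if len(participants) < 2:
            raise ValueError("different-participant pairings need >= 2 participants")
        pool = [q for q in participants if q != p]
        return pool[rng.integers(len(pool))]

    pairings = {c: [] for c in CONDITIONS}
    for p in participants:
        olds = old_trials.loc[old_trials["participant"] == p, "scene"].tolist()
        news = new_trials.loc[new_trials["participant"] == p, "scene"].tolist()
        if len(news) > len(d_set):
            raise ValueError("more new trials than dropped scenes to pair against")
        for s in olds:
            pairings["Sp-Si"].append((p, s, p, s))
        d_sp = rng.permutation(d_set)[: len(news)]
        for s, d in zip(news, d_sp):
            pairings["Sp-Di"].append((p, d, p, s))
        for s in olds:
            pairings["Dp-Si"].append((other(p), s, p, s))
        d_dp = rng.permutation(d_set)[: len(news)]
        for s, d in zip(news, d_dp):
            pairings["Dp-Di"].append((other(p), d, p, s))
    cols = ["participant_enc", "scene_enc", "participant_rec", "scene_rec"]
    return {c: pd.DataFrame(pairings[c], columns=cols) for c in CONDITIONS
            if pairings[c]}


def run_condition_cra(seqs: dict, pairings: dict, radii: dict,
                      min_line=2, min_cluster=8):
    """compute_all over every pair of every condition, for eye and head.

    ``radii`` maps target ('eye'/'head') to the recurrence radius in degrees.

    Returns
    -------
    (per_pair, summary) : one row per pair x target with the nine measures,
    and mean/SD/n (non-missing) per condition x target x measure.
    """
    rows = []
    n_missing = 0
    for cond, pairs in pairings.items():
        for rec_ in pairs.itertuples(index=False):
            enc_key = (rec_.participant_enc, rec_.scene_enc, "enc")
            rec_key = (rec_.participant_rec, rec_.scene_rec, "rec")
            if enc_key not in seqs or rec_key not in seqs:
                n_missing += 1
                continue
            for target, radius in radii.items():
                m = cra.compute_all(seqs[enc_key][target], seqs[rec_key][target],
                                    radius, min_line, min_cluster)
                rows.append({"condition": cond, "target": target,
                             "participant": rec_.participant_rec,
                             "participant_enc": rec_.participant_enc,
                             "scene_enc": rec_.scene_enc,
                             "scene_rec": rec_.scene_rec,
                             **m.as_dict()})
    if n_missing:
        warnings.warn(f"{n_missing} pair(s) skipped: no fixation sequence")
    per_pair = pd.DataFrame(rows)
    summary = per_pair.groupby(["condition", "target"])[cra.MEASURE_NAMES].agg(
        ["mean", "std", "count"])
    return per_pair, summary


def rm_anova_2x2(table: pd.DataFrame, dv="value", subject="participant",
                 image_factor="image", participant_factor="partner"
                 ) -> pd.DataFrame:
    """Two-factor within-subject ANOVA on per-participant condition means.

    ``table`` must hold one row per subject x image(Si/Di) x partner(Sp/Dp)
    cell.  Subjects with missing cells are dropped with a warning.  Returns a
    DataFrame indexed by effect with F and p (nan when variance is zero).
    """
    from statsmodels.stats.anova import AnovaRM

    counts = table.groupby(subject).size()
    complete = counts[counts == 4].index
    dropped = set(counts.index) - set(complete)
    if dropped:
        warnings.warn(f"dropping {len(dropped)} participant(s) with missing cells")
    data = table[table[subject].isin(complete)]
    if data[subject].nunique() < 2:
        raise ValueError("repeated-measures ANOVA needs >= 2 complete participants")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        with np.errstate(divide="ignore", invalid="ignore"):
            res = AnovaRM(data, depvar=dv, subject=subject,
                          within=[image_factor, participant_factor]).fit()
    tab = res.anova_table.rename(columns={"F Value": "F", "Pr > F": "p"})
    tab.index = tab.index.str.replace(
        f"{image_factor}:{participant_factor}", "interaction")
    return tab[["F", "p"]]


def exact_u_test(x, y, alternative="two-sided"):
    """Mann-Whitney U; exact null distribution when both n <= 25 and there
    are no ties, normal approximation otherwise.  Returns (U, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size <= 25 and y.size <= 25 and not ties) \
        else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


MEMORY_MEASURES = ["n_fixations", "mean_fixation_duration", "exploration_eye",
                   "exploration_head"]


def memory_table(trial_table: pd.DataFrame, measures_table: pd.DataFrame,
                 measures=tuple(MEMORY_MEASURES)):
    """Movement measures by phase and correctness, with U-test contrasts.

    Encoding trials are labelled Hit/Miss by the later recognition outcome of
    the same scene (repeated scenes only); old recognition trials split into
    Hit/Miss, new ones into CR/FA.  Empty categories skip their contrast with
    a warning.

    Returns
    -------
    (summary, contrasts) : mean/SD/n per phase x category x measure, and one
    U-test row per phase x measure (correct vs incorrect).
    """
    df = measures_table.merge(
        trial_table[["participant", "scene", "phase", "old_new", "correct"]],
        on=["participant", "scene", "phase"], how="left")

    rec_old = df[df["phase"] == "recognition_old"]
    correct_by_scene = rec_old.set_index(["participant", "scene"])["correct"]

    def category(row):
        if row["phase"] == "recognition_old":
            return "Old", "Hit" if row["correct"] else "Miss"
        if row["phase"] == "recognition_new":
            return "New", "CR" if row["correct"] else "FA"
        if row["old_new"] == "repeated":
            c = correct_by_scene.get((row["participant"], row["scene"]), None)
            if c is None:
                return None, None
            return "Encoding", "Hit" if c else "Miss"
        return None, None  # encoding trial of a dropped scene: no outcome

    cats = df.apply(lambda r: category(r), axis=1, result_type="expand")
    df = df.assign(phase_label=cats[0], category=cats[1])
    df = df.dropna(subset=["phase_label"])

    long = df.melt(id_vars=["phase_label", "category"],
                   value_vars=list(measures), var_name="measure")
    summary = long.groupby(["phase_label", "category", "measure"])["value"].agg(
        ["mean", "std", "count"])

    rows = []
    for (ph, meas), grp in long.groupby(["phase_label", "measure"]):
        pos = grp.loc[grp["category"].isin(["Hit", "CR"]), "value"].dropna()
        neg = grp.loc[grp["category"].isin(["Miss", "FA"]), "value"].dropna()
        if pos.empty or neg.empty:
            warnings.warn(f"empty category for {ph}/{meas}: contrast skipped")
            continue
        u, p = exact_u_test(pos, neg)
        rows.append({"phase": ph, "measure": meas, "U": u, "p": p,
                     "n_correct": pos.size, "n_incorrect": neg.size,
                     "mean_correct": pos.mean(), "mean_incorrect": neg.mean()})
    return summary, pd.DataFrame(rows)


def scene_heatmaps(fix_table: pd.DataFrame, target="eye", phase_kind="enc",
                   scenes=None, sigma=4.0, resolution=1.0) -> dict:
    """Per-scene heatmaps of fixation centroids pooled across participants."""
    if phase_kind == "enc":
        sub = fix_table[fix_table["phase"] == "encoding"]
    else:
        sub = fix_table[fix_table["phase"].str.startswith("recognition")]
    lon_col = f"{target}_lon"
    lat_col = f"{target}_lat"
    maps = {}
    for s, grp in sub.groupby("scene"):
        if scenes is not None and s not in scenes:
            continue
        maps[s] = spatial.make_heatmap(grp[lon_col].to_numpy(),
                                       grp[lat_col].to_numpy(),
                                       sigma=sigma, resolution=resolution)
    return maps


@dataclass
class StudyReport:
    """Bundle of every table the end-to-end pipeline produces."""

    config: StudyConfig
    trial_table: pd.DataFrame
    fix_table: pd.DataFrame
    measures_table: pd.DataFrame
    spread_eye: pd.DataFrame
    spread_head: pd.DataFrame
    radii: dict
    contrasts: dict
    cra_per_pair: pd.DataFrame
    cra_summary: pd.DataFrame
    memory_summary: pd.DataFrame
    memory_contrasts: pd.DataFrame
    anova_rec_eye: pd.DataFrame | None = None

    def write(self, outdir):
        """Export the tabular bundle as TSV files."""
        import os
        os.makedirs(outdir, exist_ok=True)
        self.trial_table.to_csv(f"{outdir}/trials.tsv", sep="\t", index=False)
        self.fix_table.to_csv(f"{outdir}/fixations.tsv", sep="\t", index=False)
        self.measures_table.to_csv(f"{outdir}/trial_measures.tsv", sep="\t",
                                   index=False)
        self.spread_eye.to_csv(f"{outdir}/spread_eye.tsv", sep="\t")
        self.spread_head.to_csv(f"{outdir}/spread_head.tsv", sep="\t")
        self.cra_per_pair.to_csv(f"{outdir}/cra_pairs.tsv", sep="\t",
                                 index=False)
        self.cra_summary.to_csv(f"{outdir}/cra_summary.tsv", sep="\t")
        self.memory_summary.to_csv(f"{outdir}/memory_summary.tsv", sep="\t")
        self.memory_contrasts.to_csv(f"{outdir}/memory_contrasts.tsv", sep="\t",
                                     index=False)
        if self.anova_rec_eye is not None:
            self.anova_rec_eye.to_csv(f"{outdir}/anova_rec_eye.tsv", sep="\t")


def run_pipeline(config: StudyConfig, seed=None, outdir=None,
                 max_dispersion=3.0, min_duration=80.0, target_rec=7.0,
                 sigma=4.0, resolution=1.0, radii=None) -> StudyReport:
    """simulate -> preprocess -> detect -> spatial + CRA + memory stages.

    Deterministic for a given config and seed; the recurrence radii are
    calibrated on the Sp-Si pairs (eye and head separately) unless given.
    """
    study = simulate_study(config, seed)
    fix_table, measures_table = detect_study(study, max_dispersion, min_duration)
    table = study.trial_table

    def phase_group(ph):
        return "encoding" if ph == "encoding" else "recognition"

    fx = fix_table.assign(phase_grp=fix_table["phase"].map(phase_group))
    _, spread_eye = spatial.spread_statistics(
        fx, lon_col="eye_lon", lat_col="eye_lat",
        group_cols=("participant", "scene", "phase_grp"), phase_col="phase_grp")
    _, spread_head = spatial.spread_statistics(
        fx, lon_col="head_lon", lat_col="head_lat",
        group_cols=("participant", "scene", "phase_grp"), phase_col="phase_grp")

    pair_seed = (int(seed if seed is not None else config.seed) + 1) % (2 ** 31)
    pairings = build_pairings(table, seed=pair_seed)
    seqs = fixation_sequences(fix_table)

    if radii is None:
        spsi = pairings["Sp-Si"]
        radii = {}
        for target in ("eye", "head"):
            pairs = [(seqs[(r.participant_enc, r.scene_enc, "enc")][target],
                      seqs[(r.participant_rec, r.scene_rec, "rec")][target])
                     for r in spsi.itertuples(index=False)
                     if (r.participant_enc, r.scene_enc, "enc") in seqs
                     and (r.participant_rec, r.scene_rec, "rec") in seqs]
            radii[target] = cra.calibrate_radius(pairs, target_rec=target_rec)

    per_pair, summary = run_condition_cra(seqs, pairings, radii)

    r_scenes = set(table.loc[table["old_new"] == "old", "scene"])
    hm = {(tg, ph): scene_heatmaps(fix_table, tg, ph, scenes=r_scenes,
                                   sigma=sigma, resolution=resolution)
          for tg in ("eye", "head") for ph in ("enc", "rec")}
    contrasts = {
        "eye_enc_rec": spatial.same_vs_different_contrast(
            hm[("eye", "enc")], hm[("eye", "rec")], seed=pair_seed),
        "head_enc_rec": spatial.same_vs_different_contrast(
            hm[("head", "enc")], hm[("head", "rec")], seed=pair_seed),
        "eye_head_enc": spatial.same_vs_different_contrast(
            hm[("eye", "enc")], hm[("head", "enc")], seed=pair_seed),
        "eye_head_rec": spatial.same_vs_different_contrast(
            hm[("eye", "rec")], hm[("head", "rec")], seed=pair_seed),
    }

    mem_summary, mem_contrasts = memory_table(table, measures_table)

    anova = None
    if table["participant"].nunique() >= 2 and len(per_pair):
        eye = per_pair[per_pair["target"] == "eye"].copy()
        eye["image"] = np.where(eye["condition"].str.endswith("Si"), "Si", "Di")
        eye["partner"] = np.where(eye["condition"].str.startswith("Sp"), "Sp", "Dp")
        cell = eye.groupby(["participant", "image", "partner"], as_index=False)[
            "rec"].mean().rename(columns={"rec": "value"})
        try:
            anova = rm_anova_2x2(cell)
        except ValueError:
            anova = None

    report = StudyReport(
        config=config, trial_table=table, fix_table=fix_table,
        measures_table=measures_table, spread_eye=spread_eye,
        spread_head=spread_head, radii=radii, contrasts=contrasts,
        cra_per_pair=per_pair, cra_summary=summary,
        memory_summary=mem_summary, memory_contrasts=mem_contrasts,
        anova_rec_eye=anova)
    if outdir is not None:
        report.write(outdir)
    return report
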