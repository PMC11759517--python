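"""Light/heavy quantification: transitions -> peptide ratios -> proteins.

The atomic signal is a fragment-ion area for one precursor, label (light =
endogenous, heavy = spiked isotope-labeled standard) and run. Quantification
proceeds in three steps:

1. per precursor and run, fragments flagged as interference or missing in
   either label are discarded; a precursor is valid only with >= 3 retained
   fragments and non-zero heavy signal, and its ratio is
   sum(light) / sum(heavy);
2. peptide ratios are rolled up to protein abundances, gated on each
   peptide's LOQ (compared on the back-computed on-column amount
   ratio x heavy spike);
3. technical replicates are averaged to biological samples and residual
   missing cells are imputed from a downshifted normal (mean shifted down
   20%, sd of the measured samples, truncated at 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TransitionRecord",
    "PrecursorMeasurement",
    "ProteinQuantMatrix",
    "flag_interference",
    "validate_precursor",
    "peptide_ratio",
    "peptide_table",
    "protein_rollup",
    "average_technical",
    "impute_missing",
    "normalize_to_condition",
]

DEFAULT_HEAVY_SPIKE_FMOL = 120.0  # assay spikes 12 or 120 fmol of standards
IMPUTATION_DOWNSHIFT = 0.20


@dataclass(frozen=True)
class TransitionRecord:
    """One fragment-ion area for one precursor, label and run."""

    sample: str
    peptide: str
    charge: int
    fragment: str
    label: str  # "light" | "heavy"
    area: float
    interference_flag: bool = False

    def __post_init__(self) -> None:
        if self.label not in ("light", "heavy"):
            raise ValueError(f"label must be light|heavy, got {self.label!r}")
        if self.area < 0:
            raise ValueError("area must be >= 0")


@dataclass
class PrecursorMeasurement:
    """Validated light/heavy measurement of one precursor in one run."""

    sample: str
    peptide: str
    charge: int
    valid: bool
    n_transitions: int
    light_sum: float = 0.0
    heavy_sum: float = 0.0
    reason: str | None = None

    @property
    def ratio(self) -> float:
        """Light/heavy ratio; NaN when invalid."""
        if not self.valid or self.heavy_sum <= 0:
            return float("nan")
        return self.light_sum / self.heavy_sum


def flag_interference(
    transitions: pd.DataFrame, factor: float = 3.0
) -> pd.DataFrame:
    """Flag light fragments whose share exceeds the heavy reference pattern.

    The heavy standard defines the expected relative fragment pattern. A
    light fragment whose share of the light total exceeds ``factor`` times
    its heavy reference share is carrying extra signal from a co-isolated
    ion and is flagged. The rule is one-sided: interference adds signal, and
    flagging under-represented fragments would punish the unaffected ones
    whose shares shrink by renormalization.

    ``transitions`` holds the rows of one (sample, peptide, charge) group.
    Returns a copy with ``interference_flag`` set; existing flags are kept.
    Without a usable heavy pattern (or with an all-zero light signal) no
    flags are added and a warning is emitted for the former.
    """
    df = transitions.copy()
    if "interference_flag" not in df.columns:
        df["interference_flag"] = False
    heavy = df[df["label"] == "heavy"].set_index("fragment")["area"]
    light = df[df["label"] == "light"].set_index("fragment")["area"]
    if heavy.empty or heavy.sum() <= 0:
        warnings.warn("no heavy reference pattern; interference not assessed")
        return df
    if light.empty or light.sum() <= 0:
        return df
    heavy_share = heavy / heavy.sum()
    light_share = light / light.sum()
    flagged = set()
    for frag, lsh in light_share.items():
        hsh = heavy_share.get(frag, 0.0)
        if lsh > factor * hsh:
            flagged.add(frag)
    mask = (df["label"] == "light") & df["fragment"].isin(flagged)
    df.loc[mask, "interference_flag"] = True
    return df


def validate_precursor(transitions: pd.DataFrame) -> PrecursorMeasurement:
    """Validate one precursor in one run and compute its label sums.

    Fragments are retained when they are present in both labels and
    unflagged in both. A precursor is valid iff >= 3 fragments are retained
    and the summed heavy area is positive; otherwise ``reason`` is
    ``"lt3_transitions"`` or ``"no_heavy"``.
    """
    samples = transitions["sample"].unique()
    peptides = transitions["peptide"].unique()
    charges = transitions["charge"].unique()
    if len(samples) != 1 or len(peptides) != 1 or len(charges) != 1:
        raise ValueError("transitions must share (sample, peptide, charge)")
    df = transitions
    if "interference_flag" in df.columns:
        df = df[~df["interference_flag"].astype(bool)]
    light = df[df["label"] == "light"].set_index("fragment")["area"]
    heavy = df[df["label"] == "heavy"].set_index("fragment")["area"]
    shared = light.index.intersection(heavy.index)
    n = len(shared)
    light_sum = float(light.loc[shared].sum()) if n else 0.0
    heavy_sum = float(heavy.loc[shared].sum()) if n else 0.0
    meas = PrecursorMeasurement(
        sample=str(samples[0]), peptide=str(peptides[0]), charge=int(charges[0]),
        valid=False, n_transitions=n, light_sum=light_sum, heavy_sum=heavy_sum,
    )
    if n < 3:
        meas.reason = "lt3_transitions"
    elif heavy_sum <= 0:
        meas.reason = "no_heavy"
    else:
        meas.valid = True
    return meas


def peptide_ratio(measurement: PrecursorMeasurement) -> float:
    """Light/heavy ratio of a valid measurement (sum light / sum heavy)."""
    if not measurement.valid:
        raise ValueError(f"invalid measurement ({measurement.reason})")
    if measurement.heavy_sum <= 0:
        raise ValueError("no_heavy")
    return measurement.light_sum / measurement.heavy_sum


def peptide_table(
    records: pd.DataFrame, interference_factor: float | None = 3.0
) -> pd.DataFrame:
    """Per-run peptide ratios from a transition report.

    Groups records by (sample, protein, peptide, charge), optionally runs
    automatic interference flagging against the heavy pattern, validates each
    precursor and returns a tidy frame with columns sample, protein, peptide,
    charge, valid, n_transitions, ratio, reason.
    """
    rows = []
    keys = ["sample", "protein", "peptide", "charge"]
    for (sample, protein, peptide, charge), grp in records.groupby(keys, sort=True):
        if interference_factor is not None:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                grp = flag_interference(grp, factor=interference_factor)
        meas = validate_precursor(grp)
        rows.append(
            {
                "sample": sample, "protein": protein, "peptide": peptide,
                "charge": charge, "valid": meas.valid,
                "n_transitions": meas.n_transitions,
                "ratio": meas.ratio if meas.valid else np.nan,
                "reason": meas.reason,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ProteinQuantMatrix:
    """Protein x sample abundances with per-cell status and design metadata.

    ``values`` is indexed by protein with one column per sample; ``status``
    has the same shape with entries ``"measured" | "imputed" | "missing"``;
    ``design`` is indexed by sample with columns condition, bafa1, bio_rep
    and (at run level) tech_rep. ``rollup_log`` records, per protein, the
    LOQ-candidate peptide set, the preferred all-sample set and which was
    used; ``imputation_log`` records seed and draw index per imputed cell.
    """

    values: pd.DataFrame
    status: pd.DataFrame
    design: pd.DataFrame
    peptides_used: dict[str, list[str]] = field(default_factory=dict)
    rollup_log: dict[str, dict] = field(default_factory=dict)
    imputation_log: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.status.index) or not (
            self.values.columns.equals(self.status.columns)
        ):
            raise ValueError("values and status must be aligned")

    @property
    def proteins(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def to_tidy(self) -> pd.DataFrame:
        """Long-format frame: protein, sample, value, status."""
        v = self.values.stack(future_stack=True).rename("value")
        s = self.status.stack(future_stack=True).rename("status")
        out = pd.concat([v, s], axis=1).reset_index()
        out.columns = ["protein", "sample", "value", "status"]
        return out


def _loq_map(lodq: pd.DataFrame | None) -> Mapping[str, float] | None:
    if lodq is None:
        return None
    df = lodq
    if "quantifiable" in df.columns:
        df = df[df["quantifiable"].astype(bool)]
    # per peptide, use the most sensitive quantifiable precursor
    return df.groupby("peptide")["loq"].min().to_dict()


def protein_rollup(
    peptides: pd.DataFrame,
    design: pd.DataFrame,
    lodq: pd.DataFrame | None = None,
    *,
    heavy_spike: float = DEFAULT_HEAVY_SPIKE_FMOL,
) -> ProteinQuantMatrix:
    """Roll peptide ratios up to protein abundances with LOQ gating.

    A peptide measurement is "above LOQ" when its back-computed on-column
    amount, ratio x ``heavy_spike`` (fmol), exceeds the peptide's LOQ; with
    ``lodq=None`` every valid measurement counts as above. Peptides above
    LOQ in at least one run form a protein's candidate set; if the subset of
    candidates valid in *every* run is non-empty, only that set is used
    (protein value = mean of its peptide ratios per run); otherwise the full
    candidate set is used with per-run missingness. Proteins with an empty
    candidate set are missing everywhere. Both sets and the choice are
    recorded in ``rollup_log``.
    """
    pep2prot = peptides.groupby("peptide")["protein"].unique()
    multi = pep2prot[pep2prot.map(len) > 1]
    if len(multi):
        raise ValueError(
            f"peptides mapped to multiple proteins: {sorted(multi.index)}"
        )
    loqs = _loq_map(lodq)
    samples = list(design.index)
    df = peptides.copy()
    if loqs is None:
        df["above_loq"] = df["valid"]
    else:
        loq = df["peptide"].map(loqs)
        df["above_loq"] = df["valid"] & (df["ratio"] * heavy_spike > loq)
        df.loc[loq.isna(), "above_loq"] = False  # no calibration -> not gateable

    proteins = sorted(df["protein"].unique())
    values = pd.DataFrame(np.nan, index=proteins, columns=samples, dtype=float)
    status = pd.DataFrame("missing", index=proteins, columns=samples)
    peptides_used: dict[str, list[str]] = {}
    rollup_log: dict[str, dict] = {}

    for protein, grp in df.groupby("protein", sort=True):
        # one row per (peptide, sample); several charge states of a peptide
        # are averaged after validation
        agg = (
            grp.groupby(["peptide", "sample"])
            .agg(
                valid=("valid", "any"),
                above=("above_loq", "any"),
                ratio=("ratio", "mean"),
            )
            .reset_index()
        )
        candidates = sorted(agg.loc[agg["above"], "peptide"].unique())
        cand = agg[agg["peptide"].isin(candidates)]
        preferred = []
        for pep, pgrp in cand.groupby("peptide"):
            ok = pgrp.set_index("sample")["valid"].reindex(samples, fill_value=False)
            if bool(ok.all()):
                preferred.append(pep)
        use = preferred if preferred else candidates
        mode = "all_samples" if preferred else ("any_replicate" if candidates else "none")
        rollup_log[str(protein)] = {
            "candidates": candidates,
            "all_sample_set": sorted(preferred),
            "used": sorted(use),
            "mode": mode,
        }
        peptides_used[str(protein)] = sorted(use)
        if not use:
            continue
        sel = agg[agg["peptide"].isin(use) & agg["valid"]]
        per_sample = sel.groupby("sample")["ratio"].mean()
        for sample, val in per_sample.items():
            if sample in values.columns and np.isfinite(val):
                values.loc[protein, sample] = val
                status.loc[protein, sample] = "measured"

    return ProteinQuantMatrix(
        values=values, status=status, design=design.copy(),
        peptides_used=peptides_used, rollup_log=rollup_log,
    )


def average_technical(matrix: ProteinQuantMatrix) -> ProteinQuantMatrix:
    """Average technical replicates into biological samples.

    Biological samples are the (condition, bafa1, bio_rep) groups of the
    design. A cell is measured if any technical replicate was measured (the
    mean is over measured replicates only); otherwise missing. Imputation is
    meant to run on the result, i.e. at biological-sample level.
    """
    design = matrix.design
    keys = ["condition", "bafa1", "bio_rep"]
    groups = design.groupby(keys, sort=True)
    bio_ids, bio_rows, val_cols, stat_cols = [], [], [], []
    for (cond, baf, bio), grp in groups:
        bio_id = f"{cond}{'+BafA1' if baf else ''}_b{bio}"
        bio_ids.append(bio_id)
        bio_rows.append({"condition": cond, "bafa1": baf, "bio_rep": bio})
        cols = [s for s in grp.index if s in matrix.values.columns]
        vals = matrix.values[cols]
        meas = matrix.status[cols] == "measured"
        val_cols.append(vals.where(meas).mean(axis=1))
        stat_cols.append(meas.any(axis=1))
    values = pd.concat(val_cols, axis=1)
    values.columns = bio_ids
    measured = pd.concat(stat_cols, axis=1)
    measured.columns = bio_ids
    status = measured.map(lambda m: "measured" if m else "missing")
    bio_design = pd.DataFrame(bio_rows, index=bio_ids)
    return ProteinQuantMatrix(
        values=values, status=status, design=bio_design,
        peptides_used=dict(matrix.peptides_used),
        rollup_log=dict(matrix.rollup_log),
    )


def impute_missing(
    matrix: ProteinQuantMatrix,
    seed: int = 0,
    *,
    n_draws: int = 1,
    downshift: float = IMPUTATION_DOWNSHIFT,
) -> ProteinQuantMatrix:
    """Impute missing cells from a downshifted truncated normal.

    For a protein with >= 2 measured samples, each missing cell draws from
    Normal((1 - downshift) * mean_measured, sd_measured) truncated at 0 — a
    conservative abundance estimate for samples where no peptide was valid.
    With ``n_draws > 1`` the cell value is the mean of the draws. Cells of
    proteins with fewer than 2 measured samples stay missing with reason
    ``"insufficient_support"``. Every imputed cell's seed and draw index are
    recorded in ``imputation_log``; measured cells are untouched.
    """
    rng = np.random.default_rng(seed)
    values = matrix.values.copy()
    status = matrix.status.copy()
    log: list[dict] = []
    draw_index = 0
    for protein in values.index:
        row_status = status.loc[protein]
        measured = values.loc[protein, row_status == "measured"].astype(float)
        missing_cols = [c for c in values.columns if row_status[c] == "missing"]
        if not missing_cols:
            continue
        if len(measured) < 2:
            for col in missing_cols:
                log.append(
                    {"protein": protein, "sample": col, "imputed": False,
                     "reason": "insufficient_support"}
                )
            continue
        mu = float(measured.mean())
        sd = float(measured.std(ddof=1))
        target = (1.0 - downshift) * mu
        for col in missing_cols:
            if sd == 0:
                draws = np.full(n_draws, target)
            else:
                a = (0.0 - target) / sd  # truncate at zero
                draws = sps.truncnorm.rvs(
                    a, np.inf, loc=target, scale=sd, size=n_draws, random_state=rng
                )
            values.loc[protein, col] = float(np.mean(draws))
            status.loc[protein, col] = "imputed"
            log.append(
                {"protein": protein, "sample": col, "imputed": True,
                 "seed": seed, "draw_index": draw_index, "n_draws": n_draws}
            )
            draw_index += n_draws
    return ProteinQuantMatrix(
        values=values, status=status, design=matrix.design.copy(),
        peptides_used=dict(matrix.peptides_used),
        rollup_log=dict(matrix.rollup_log),
        imputation_log=matrix.imputation_log + log,
    )


def normalize_to_condition(
    matrix: ProteinQuantMatrix, condition: str = "DMEM", bafa1: bool = False
) -> ProteinQuantMatrix:
    """Scale each protein so the reference condition's mean equals 1.

    Applied last, for presentation (growth-condition reference bars); flux,
    CV and ANOVA are scale-invariant and do not depend on it.
    """
    design = matrix.design
    ref = design[(design["condition"] == condition) & (design["bafa1"] == bafa1)]
    if ref.empty:
        raise ValueError(f"reference condition {condition!r} not in design")
    cols = [s for s in ref.index if s in matrix.values.columns]
    ref_mean = matrix.values[cols].mean(axis=1)
    if (ref_mean <= 0).any() or ref_mean.isna().any():
        bad = list(ref_mean.index[(ref_mean <= 0) | ref_mean.isna()])
        warnings.warn(f"reference mean undefined for {bad}; left unscaled")
        ref_mean = ref_mean.where(ref_mean > 0, 1.0).fillna(1.0)
    values = matrix.values.div(ref_mean, axis=0)
    return ProteinQuantMatrix(
        values=values, status=matrix.status.copy(), design=design.copy(),
        peptides_used=dict(matrix.peptides_used),
        rollup_log=dict(matrix.rollup_log),
        imputation_log=list(matrix.imputation_log),
    )
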