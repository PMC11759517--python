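"""Synthetic PRM data with known ground truth.

Emulates the two experiment types the pipeline consumes: calibration runs
(serial dilutions of spiked synthetic peptides plus blanks) and treatment
experiments (conditions x +/-BafA1 x biological x technical replicates with
known protein effects and flux). Every generated dataset is accompanied by
its :class:`SimulationTruth` so recovery can be tested end to end.

Noise model
-----------
All noise is multiplicative lognormal with unit mean, parameterized by a
target CV%: sigma_log = sqrt(ln(1 + (cv/100)^2)). Technical noise is drawn
once per (run, protein) and shared by that protein's peptides and fragments
— after heavy normalization removes run-level scale, this residual factor is
exactly what the assay's protein-level technical CV measures, so the CV
estimated by the stats module matches the injected value. Biological noise
is drawn per (protein, dish), fragment-level integration noise per fragment
area, and a run-level intensity scale (which cancels in light/heavy ratios)
per run. Light signals whose back-computed on-column amount falls below a
peptide's LOD are dropped, producing realistic missingness.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PeptideTruth",
    "SimulationTruth",
    "make_truth",
    "make_design",
    "generate_calibration",
    "generate_experiment",
]

_AA = "ACDEFGHILNPQSTVWY"  # no K/R/M internally: fully tryptic, oxidation-safe


def _lognormal_factor(rng: np.random.Generator, cv_percent: float, size=None):
    """Unit-mean multiplicative lognormal noise at the given CV%."""
    if cv_percent <= 0:
        return np.ones(size) if size is not None else 1.0
    cv = cv_percent / 100.0
    sigma = math.sqrt(math.log1p(cv * cv))
    return np.exp(rng.normal(-0.5 * sigma * sigma, sigma, size=size))


@dataclass
class PeptideTruth:
    """True response curve and fragment pattern of one peptide precursor."""

    peptide: str
    protein: str
    charge: int
    baseline: float  # intensity plateau (area units)
    changepoint: float  # fmol
    slope: float  # area units per fmol
    lod: float = 0.0  # fmol; light signal below this is dropped
    fragments: dict[str, float] = field(default_factory=dict)  # name -> share


@dataclass
class SimulationTruth:
    """Ground truth of a simulated assay.

    ``condition_log2fc[protein][condition]`` is the protein's abundance
    log2 fold-change in that condition relative to baseline;
    ``flux[protein][condition]`` is the true +BafA1/-BafA1 ratio of means
    (the -BafA1 arm is the baseline abundance divided by the flux).
    """

    peptides: list[PeptideTruth]
    baseline_amount: dict[str, float]  # protein -> fmol on column
    condition_log2fc: dict[str, dict[str, float]] = field(default_factory=dict)
    flux: dict[str, dict[str, float]] = field(default_factory=dict)
    cv_technical: float = 5.0  # % — per (run, protein)
    cv_biological: float = 5.0  # % — per (protein, dish)
    cv_fragment: float = 1.0  # % — per fragment area
    cv_run_scale: float = 10.0  # % — run-level intensity scale (cancels in ratios)
    blank_sd_frac: float = 0.25  # blank noise sd as a fraction of the baseline
    heavy_spike: float = 120.0  # fmol of heavy standard per sample
    seed: int = 0

    @property
    def proteins(self) -> list[str]:
        return sorted(self.baseline_amount)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1), encoding="utf-8")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationTruth":
        peptides = [PeptideTruth(**p) for p in d.pop("peptides")]
        return cls(peptides=peptides, **d)

    @classmethod
    def load(cls, path: str | Path) -> "SimulationTruth":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


def make_truth(
    n_proteins: int = 10,
    peptides_per_protein: int = 2,
    fragments_per_peptide: int = 4,
    *,
    seed: int = 0,
    cv_technical: float = 5.0,
    cv_biological: float = 5.0,
    cv_fragment: float = 1.0,
    cv_run_scale: float = 10.0,
    blank_sd_frac: float = 0.25,
    heavy_spike: float = 120.0,
    condition_log2fc: dict[str, dict[str, float]] | None = None,
    flux: dict[str, dict[str, float]] | None = None,
    lod: float = 0.0,
) -> SimulationTruth:
    """Draw a random but reproducible simulation truth.

    Protein names are ``PROT001``.. and peptide sequences random tryptic-like
    strings (terminal K/R, no internal K/R/M). Baseline on-column amounts are
    log-uniform in 5..50 fmol, response slopes log-uniform in 1e4..1e5 area
    units per fmol, changepoints in 0.02..0.2 fmol, and fragment shares come
    from a flat Dirichlet, drawn once per peptide and fixed across samples.
    """
    rng = np.random.default_rng(seed)
    proteins = [f"PROT{i + 1:03d}" for i in range(n_proteins)]
    peptides: list[PeptideTruth] = []
    seen: set[str] = set()
    for prot in proteins:
        for _ in range(peptides_per_protein):
            while True:
                length = int(rng.integers(8, 15))
                seq = "".join(rng.choice(list(_AA), size=length)) + str(
                    rng.choice(["K", "R"])
                )
                if seq not in seen:
                    seen.add(seq)
                    break
            shares = rng.dirichlet(np.full(fragments_per_peptide, 4.0))
            fragments = {
                f"y{j + 3}": float(s) for j, s in enumerate(shares)
            }
            peptides.append(
                PeptideTruth(
                    peptide=seq,
                    protein=prot,
                    charge=2,
                    baseline=float(rng.uniform(100, 400)),
                    changepoint=float(np.exp(rng.uniform(math.log(0.02), math.log(0.2)))),
                    slope=float(np.exp(rng.uniform(math.log(1e4), math.log(1e5)))),
                    lod=float(lod),
                    fragments=fragments,
                )
            )
    baseline_amount = {
        p: float(np.exp(rng.uniform(math.log(5.0), math.log(50.0))))
        for p in proteins
    }
    return SimulationTruth(
        peptides=peptides,
        baseline_amount=baseline_amount,
        condition_log2fc=condition_log2fc or {},
        flux=flux or {},
        cv_technical=cv_technical,
        cv_biological=cv_biological,
        cv_fragment=cv_fragment,
        cv_run_scale=cv_run_scale,
        blank_sd_frac=blank_sd_frac,
        heavy_spike=heavy_spike,
        seed=seed,
    )


def make_design(
    conditions: Sequence[str],
    *,
    bafa1: Sequence[bool] = (False, True),
    n_bio: int = 3,
    n_tech: int = 3,
) -> pd.DataFrame:
    """Factorial sample design: conditions x +/-BafA1 x bio reps x tech reps."""
    rows = []
    for cond in conditions:
        for baf in bafa1:
            for b in range(1, n_bio + 1):
                for t in range(1, n_tech + 1):
                    sample = f"{cond}{'+BafA1' if baf else ''}_b{b}_t{t}"
                    rows.append(
                        {"sample": sample, "condition": cond, "bafa1": bool(baf),
                         "bio_rep": b, "tech_rep": t}
                    )
    return pd.DataFrame(rows).set_index("sample")


_COLUMNS = [
    "sample", "condition", "bafa1", "bio_rep", "tech_rep", "protein",
    "peptide", "charge", "fragment", "label", "area",
]


def generate_calibration(
    truth: SimulationTruth,
    series: Sequence[float],
    n_reps: int = 3,
    n_blanks: int = 3,
    seed: int = 0,
    *,
    include_background: bool = True,
    background_peptide: str = "QSVENDIHGLR",
) -> pd.DataFrame:
    """Transition report for a dilution-series calibration experiment.

    ``series`` comes from :func:`prmflux.calibration.make_dilution_series`.
    Per concentration x replicate run, each peptide's light response follows
    its bilinear curve times the injected noise; blank runs draw from the
    baseline plus truncated Gaussian blank noise. Heavy areas sit at the
    nominal spike with independent noise. A constant background-matrix
    peptide (keratin 18) is included so run-level normalization is
    exercised. The output carries a ``concentration_fmol`` column and is
    deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    runs: list[tuple[str, float, int]] = []
    for i, conc in enumerate(series):
        for rep in range(1, n_reps + 1):
            runs.append((f"cal_c{i + 1}_r{rep}", float(conc), rep))
    for rep in range(1, n_blanks + 1):
        runs.append((f"blank_r{rep}", 0.0, rep))

    rows = []
    for sample, conc, rep in runs:
        run_scale = float(_lognormal_factor(rng, truth.cv_run_scale))
        for pep in truth.peptides:
            tech = float(_lognormal_factor(rng, truth.cv_technical))
            if conc > 0:
                light_total = (
                    pep.baseline + pep.slope * max(0.0, conc - pep.changepoint)
                ) * tech
            else:
                noise = rng.normal(0.0, truth.blank_sd_frac * pep.baseline)
                light_total = max(0.0, pep.baseline + noise)
            heavy_total = pep.slope * truth.heavy_spike * float(
                _lognormal_factor(rng, truth.cv_technical)
            )
            for frag, share in pep.fragments.items():
                fl = float(_lognormal_factor(rng, truth.cv_fragment))
                fh = float(_lognormal_factor(rng, truth.cv_fragment))
                base = {
                    "sample": sample, "condition": "calibration", "bafa1": False,
                    "bio_rep": 1, "tech_rep": rep, "protein": pep.protein,
                    "peptide": pep.peptide, "charge": pep.charge, "fragment": frag,
                }
                rows.append({**base, "label": "light",
                             "area": light_total * share * fl * run_scale,
                             "concentration_fmol": conc})
                rows.append({**base, "label": "heavy",
                             "area": heavy_total * share * fh * run_scale,
                             "concentration_fmol": conc})
        if include_background:
            bg = 1e6 * run_scale * float(_lognormal_factor(rng, 2.0))
            rows.append({
                "sample": sample, "condition": "calibration", "bafa1": False,
                "bio_rep": 1, "tech_rep": rep, "protein": "KRT18",
                "peptide": background_peptide, "charge": 2, "fragment": "y6",
                "label": "light", "area": bg, "concentration_fmol": conc,
            })
    return pd.DataFrame(rows, columns=_COLUMNS + ["concentration_fmol"])


def generate_experiment(
    truth: SimulationTruth,
    design: pd.DataFrame,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Transition report + design for a treatment experiment.

    Per protein, the true on-column amount in a sample is

        baseline_amount * 2**log2fc(condition) * (1 if +BafA1 else 1/flux)
        * biological factor (per dish) * technical factor (per run),

    so the +BafA1/-BafA1 ratio of arm means equals the protein's true flux.
    Light fragment areas distribute that amount over the peptide's fixed
    fragment pattern at its response slope; heavy areas sit at the nominal
    spike. Light signal below a peptide's LOD is dropped entirely (the heavy
    standard is always present), which downstream appears as a missing
    precursor. Returns ``(records, design)``; serialize ``truth`` alongside.
    """
    rng = np.random.default_rng(seed)
    # biological factors per (protein, condition, bafa1, bio_rep)
    dishes = design.reset_index()[["condition", "bafa1", "bio_rep"]].drop_duplicates()
    bio_factor: dict[tuple, float] = {}
    for _, dish in dishes.iterrows():
        for prot in truth.proteins:
            key = (prot, dish["condition"], bool(dish["bafa1"]), int(dish["bio_rep"]))
            bio_factor[key] = float(_lognormal_factor(rng, truth.cv_biological))

    rows = []
    for sample, meta in design.iterrows():
        cond, baf = meta["condition"], bool(meta["bafa1"])
        run_scale = float(_lognormal_factor(rng, truth.cv_run_scale))
        tech = {
            prot: float(_lognormal_factor(rng, truth.cv_technical))
            for prot in truth.proteins
        }
        for pep in truth.peptides:
            prot = pep.protein
            fc = truth.condition_log2fc.get(prot, {}).get(cond, 0.0)
            fx = truth.flux.get(prot, {}).get(cond, 1.0)
            amount = truth.baseline_amount[prot] * 2.0**fc
            if not baf:
                amount /= fx
            amount *= bio_factor[(prot, cond, baf, int(meta["bio_rep"]))]
            amount *= tech[prot]
            light_missing = amount < pep.lod
            light_total = pep.slope * amount
            heavy_total = pep.slope * truth.heavy_spike
            for frag, share in pep.fragments.items():
                fl = float(_lognormal_factor(rng, truth.cv_fragment))
                fh = float(_lognormal_factor(rng, truth.cv_fragment))
                base = {
                    "sample": sample, "condition": cond, "bafa1": baf,
                    "bio_rep": int(meta["bio_rep"]), "tech_rep": int(meta["tech_rep"]),
                    "protein": prot, "peptide": pep.peptide, "charge": pep.charge,
                    "fragment": frag,
                }
                if not light_missing:
                    rows.append({**base, "label": "light",
                                 "area": light_total * share * fl * run_scale})
                rows.append({**base, "label": "heavy",
                             "area": heavy_total * share * fh * run_scale})
    return pd.DataFrame(rows, columns=_COLUMNS), design.copy()
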