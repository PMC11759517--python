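import numpy as np
import pandas as pd
import pytest

from prmflux import synth


def transition_frame(
    light: dict[str, float],
    heavy: dict[str, float],
    *,
    sample: str = "s1",
    protein: str = "P1",
    peptide: str = "ELVISLIVESK",
    charge: int = 2,
    flags: set[str] | None = None,
) -> pd.DataFrame:
    """Build a one-precursor transition frame from fragment->area dicts."""
    rows = []
    for label, areas in (("light", light), ("heavy", heavy)):
        for frag, area in areas.items():
            rows.append(
                {
                    "sample": sample, "condition": "DMEM", "bafa1": False,
                    "bio_rep": 1, "tech_rep": 1, "protein": protein,
                    "peptide": peptide, "charge": charge, "fragment": frag,
                    "label": label, "area": float(area),
                    "interference_flag": bool(flags and frag in flags and label == "light"),
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def flux_truth():
    """Truth with a known flux of 2 in DMEM for every protein."""
    proteins = [f"PROT{i:03d}" for i in range(1, 7)]
    return synth.make_truth(
        6, 2, 4, seed=101,
        flux={p: {"DMEM": 2.0} for p in proteins},
    )


@pytest.fixture(scope="session")
def flux_experiment(flux_truth):
    design = synth.make_design(["DMEM"], n_bio=3, n_tech=3)
    records, design = synth.generate_experiment(flux_truth, design, seed=102)
    return records, design
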