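import numpy as np
import pandas as pd
import pytest

import isletkit as ik


@pytest.fixture(scope="session")
def preset_study():
    """The five-model synthetic study at seed 1 (shared across tests)."""
    return ik.simulate_counts(ik.default_config(seed=1))


@pytest.fixture(scope="session")
def preset_de(preset_study):
    """DE tables for one LKB1-null and one AMPK-null model of the preset."""
    study, truth = preset_study
    return {
        "Ins1LKB1KO": ik.de_table(study["Ins1LKB1KO"]),
        "Ins1AMPKdKO": ik.de_table(study["Ins1AMPKdKO"]),
    }


@pytest.fixture()
def tiny_counts():
    """A hand-sized two-condition count matrix (4 genes, 2+2 samples)."""
    genes = pd.Index(["gA", "gB", "gC", "gD"], name="gene")
    counts = pd.DataFrame(
        {
            "m:KO:1": [100, 10, 0, 55],
            "m:KO:2": [110, 12, 0, 60],
            "m:WT:1": [50, 11, 0, 58],
            "m:WT:2": [55, 9, 0, 52],
        },
        index=genes,
    )
    samples = pd.DataFrame(
        [["m", "KO", 1], ["m", "KO", 2], ["m", "WT", 1], ["m", "WT", 2]],
        index=counts.columns,
        columns=["model", "condition", "replicate"],
    )
    lengths = pd.Series([1000, 2000, 1500, 800], index=genes, name="length")
    return ik.CountMatrix(counts=counts, samples=samples, lengths=lengths, name="m")


def make_de_frame(rows):
    """Build a DE table from (gene, fc, p, e, present) tuples for one model."""
    model = rows[0][0]
    recs = []
    for model, gene, fc, p, e, present in rows:
        recs.append(
            {
                "gene": gene,
                "model": model,
                "fc": fc,
                "log2fc": np.log2(fc) if fc is not None and fc > 0 else np.nan,
                "p": p,
                "e": e,
                "mean_rpkm_ko": 10.0,
                "mean_rpkm_wt": 10.0,
                "present": present,
                "tested": present and p is not None,
            }
        )
    df = pd.DataFrame(recs)
    df["fc"] = df["fc"].astype(float)
    df["p"] = df["p"].astype(float)
    df["e"] = df["e"].astype(float)
    return df
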