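import numpy as np
import pandas as pd
import pytest

from matmr import SimulationConfig, SummaryStatTable

#: SBP->birthweight path (g per SD SBP) used as the study condition in
#: simulation-based tests: the published mediation arithmetic (~12 g lower
#: birthweight per SD urate at 0.07 SD SBP per SD urate) implies ~-171 g/SD.
B_SBP_TO_BW = -12.0 / 0.07


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def base_config():
    return SimulationConfig(n_duos=20_000, b_sbp_to_bw=B_SBP_TO_BW, seed=11)


def make_table(rows, trait="trait", unit="unit") -> SummaryStatTable:
    """Build a SummaryStatTable from (rsid, ea, oa, eaf, beta, se) tuples."""
    df = pd.DataFrame(
        rows, columns=["rsid", "effect_allele", "other_allele", "eaf", "beta", "se"]
    )
    df["pval"] = 0.5
    df["n"] = 1000
    return SummaryStatTable(trait, unit, df)


@pytest.fixture
def tsv_writer(tmp_path):
    def _write(df: pd.DataFrame, name: str):
        path = tmp_path / name
        df.to_csv(path, sep="\t", index=False)
        return path

    return _write
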