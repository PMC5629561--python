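import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from splicemod.datatypes import ExpressionMatrix, PsiMatrix, TFTargetMap

settings.register_profile(
    "ci", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


@pytest.fixture
def samples():
    return [f"S{i:02d}" for i in range(1, 11)]


@pytest.fixture
def small_expr(samples):
    rng = np.random.default_rng(42)
    df = pd.DataFrame(
        rng.uniform(0, 100, size=(4, 10)),
        index=["TF1", "TF2", "G1", "G2"], columns=samples)
    return ExpressionMatrix(df)


@pytest.fixture
def small_psi(samples):
    rng = np.random.default_rng(7)
    df = pd.DataFrame(
        rng.uniform(0.05, 0.95, size=(2, 10)),
        index=["E1", "E2"], columns=samples)
    return PsiMatrix(df, event_gene={"E1": "MOD1", "E2": "MOD2"})


@pytest.fixture
def small_pairs():
    return TFTargetMap({("TF1", "G1"), ("TF1", "G2"),
                        ("TF2", "G1"), ("TF2", "G2")})


@pytest.fixture
def expr_file(tmp_path):
    """Well-formed 3-gene x 4-sample expression TSV."""
    p = tmp_path / "expr.tsv"
    p.write_text(
        "gene_id\tS1\tS2\tS3\tS4\n"
        "TP53\t1.0\t2.5\t0\t10\n"
        "MDM2\t3.0\tNA\t4.5\t6\n"
        "NR3C1\t0.5\t0.5\t0.5\t0.5\n")
    return p


@pytest.fixture
def psi_file(tmp_path):
    """2-event x 4-sample PSI TSV with a host-gene column."""
    p = tmp_path / "psi.tsv"
    p.write_text(
        "event_id\tgene\tS1\tS2\tS3\tS4\n"
        "E1\tMDM2\t0\t0.5\t1\tNA\n"
        "E2\tTP53\t0.25\t0.75\t0.1\t0.9\n")
    return p
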