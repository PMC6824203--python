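import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_gwas_df(snps, betas, ses, a1="A", a2="G", freq=0.3, n=1000):
    k = len(snps)
    return pd.DataFrame({
        "SNP": snps,
        "A1": [a1] * k if isinstance(a1, str) else a1,
        "A2": [a2] * k if isinstance(a2, str) else a2,
        "freq": [freq] * k,
        "b": betas,
        "se": ses,
        "p": 2 * __import__("scipy.stats", fromlist=["norm"]).norm.sf(
            np.abs(np.asarray(betas) / np.asarray(ses))),
        "N": [n] * k,
    })


@pytest.fixture
def gwas_file(tmp_path):
    """Write a GWAS-dialect file from raw lines and return its path."""

    def _write(rows, header="SNP A1 A2 freq b se p N"):
        path = tmp_path / "study.ma"
        path.write_text("\n".join([header] + rows) + "\n")
        return path

    return _write


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """A small but complete synthetic dataset shared across tests."""
    from smr_integrate.synthetic_data import SimConfig, simulate

    out = tmp_path_factory.mktemp("smallsim")
    cfg = SimConfig(n_snps=2200, n_probes_eqtl=40, n_probes_mqtl=60,
                    n_causal_probes=4, n_shared_causal=2, snps_per_probe=5,
                    n_chromosomes=4, seed=7)
    res = simulate(cfg, out)
    return res
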