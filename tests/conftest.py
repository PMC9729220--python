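import pandas as pd
import pytest

import lesionbypass as lb


@pytest.fixture(scope="session")
def std_strand():
    return lb.ChiralStrand.from_str(lb.STD_SEQ, "STD")


@pytest.fixture(scope="session")
def com20_strand():
    return lb.ChiralStrand.from_str(lb.COM20_SEQ, "COM20")


@pytest.fixture(scope="session")
def constructs_g():
    return lb.build_constructs("G")


@pytest.fixture(scope="session")
def decode_g():
    return lb.decode_table("G")


def make_band_table(e_by_construct, decode, i20_std=1.0, i24=1.0, scale=1.0):
    """Hand-build a minimal band table realizing given incorporation ratios.

    Each construct's 20-mer intensity is e_k * i20_std (omitted when zero,
    i.e. band absent), with equal 24-mer loading bands everywhere.
    """
    rows = []
    samples = list(decode.construct_names) + ["STD"]
    for s in samples:
        rows.append([s, lb.PROTOCOL_EH, 24, i24 * scale])
        rows.append([s, lb.PROTOCOL_PH, 23, i24 * scale])  # flank fragment band
    rows.append(["STD", lb.PROTOCOL_PH, 20, i20_std * scale])
    for s in decode.construct_names:
        ek = e_by_construct.get(s, 0.0)
        if ek > 0:
            rows.append([s, lb.PROTOCOL_PH, 20, ek * i20_std * scale])
    return pd.DataFrame(rows, columns=["sample", "protocol", "length_nt", "intensity"])


def recovery_tables(lesion, beta, pi, *, n_templates=100_000, sigma=0.05,
                    seeds=tuple(range(1, 11)), pool_seed=None, expected=False):
    """Simulate one scenario and return (replicate band tables, decode table)."""
    cfg = lb.ScenarioConfig(
        lesion=lesion, beta=beta, pi=pi, n_templates=n_templates, sigma=sigma,
        replicates=len(seeds), seeds=tuple(seeds), pool_seed=pool_seed,
        expected=expected,
    )
    pools, decode = lb.simulate_pools(cfg)
    tables = [lb.replicate_band_table(pools, cfg, r) for r in range(len(seeds))]
    return tables, decode
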