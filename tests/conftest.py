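import numpy as np
import pandas as pd
import pytest

from stemvar import synth


@pytest.fixture(scope="session")
def small_config():
    """A fast lineage configuration reused across tests."""
    return synth.SimConfig(
        seed=7,
        n_subclones=2,
        subclone_fractions=(0.5, 0.3),
        ancestral_mutations=120,
        uv_rate_per_subclone=150.0,
        doublet_fraction=0.1,
        culture_rate_per_passage=8.0,
        passages=10,
        neutral_tail_mutations=120,
        depth_mean=60.0,
        error_rate=1e-3,
        n_error_sites=400,
        n_germline_sites=20,
    )


@pytest.fixture(scope="session")
def lineage(small_config):
    """(parent truth, tracks, derived truth, paired counts) for one line."""
    parent, tracks = synth.simulate_parent_population(small_config)
    derived = synth.simulate_derived_line(parent, small_config, 0, seed=101)
    counts = synth.sample_read_counts(parent, derived, small_config, seed=102)
    return parent, tracks, derived, counts


def make_counts(rows):
    """Build a minimal paired-counts frame from (pos, p_ref, p_alt, d_ref, d_alt)."""
    df = pd.DataFrame(
        rows, columns=["pos", "parent_ref", "parent_alt", "derived_ref", "derived_alt"]
    )
    df.insert(0, "chrom", "chr1")
    df["ref"] = "C"
    df["alt"] = "T"
    df["context"] = "ACA"
    df["germline_flag"] = False
    df["mask_low_mappability"] = False
    df["mask_cnv"] = False
    return df


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
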