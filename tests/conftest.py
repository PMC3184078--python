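import numpy as np
import pytest

from promnet.motif_io import Promoter, PWMatrix


@pytest.fixture
def one_hot_pwm():
    """Sharp 8-position matrix for the (non-palindromic) consensus AAACCGGG."""
    consensus = "AAACCGGG"
    counts = np.zeros((8, 4))
    for i, b in enumerate(consensus):
        counts[i, "ACGT".index(b)] = 10.0
    return PWMatrix.from_counts("ONEHOT", counts, pseudocount=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_promoter(sequence, promoter_id="P1", gene_id="G1", tss_offset=None):
    if tss_offset is None:
        tss_offset = len(sequence)  # whole window upstream of TSS
    return Promoter(promoter_id, gene_id, sequence, tss_offset)


def random_sequence(rng, n, alphabet="ACGT"):
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), n))


@pytest.fixture(scope="session")
def reference_run():
    """One seeded reference cohort pushed through the analysis core.

    Session-scoped: the cohort, thresholds, scans, enrichment and ranking
    are shared by pipeline-level tests.
    """
    from promnet import enrichment_network as net
    from promnet import pwm_scan, synthetic_data as sd

    spec = sd.reference_cohort_spec(seed=0)
    cohort = sd.generate_cohort(spec)
    profile = pwm_scan.calibrate_profile(cohort.pwms, cohort.background_promoters)
    target_hits = pwm_scan.scan_promoters(cohort.pwms, cohort.target_promoters, profile)
    background_hits = pwm_scan.scan_promoters(
        cohort.pwms, cohort.background_promoters, profile)
    ori = net.compute_ori(target_hits, cohort.target_promoters,
                          background_hits, cohort.background_promoters)
    return {
        "spec": spec,
        "cohort": cohort,
        "profile": profile,
        "target_hits": target_hits,
        "background_hits": background_hits,
        "ori": ori,
    }
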