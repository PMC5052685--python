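import pytest
from hypothesis import HealthCheck, settings

import parclipkit as pk

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_cfg() -> pk.SimulationConfig:
    """A compact study: 60 transcripts, two replicates, default effect sizes."""
    return pk.SimulationConfig(
        seed=11,
        n_transcripts=60,
        region_lengths=(60, 400, 140),
        reads_per_site=20.0,
    )


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    transcripts, truth = pk.generate_transcriptome(small_cfg)
    reads1 = pk.simulate_parclip_replicate(transcripts, truth, small_cfg, 1)
    reads2 = pk.simulate_parclip_replicate(transcripts, truth, small_cfg, 2)
    return transcripts, truth, reads1, reads2


def call_sites_for_replicate(transcripts, reads, params=None):
    """Full per-replicate calling chain used by several tests."""
    params = params or pk.SiteCallingParams()
    tx_by_id = {t.id: t for t in transcripts}
    by_tx = {}
    for r in reads:
        by_tx.setdefault(r.transcript_id, []).append(r)
    sites = []
    for tid in sorted(by_tx):
        profile = pk.profile_conversions(by_tx[tid], tx_by_id[tid])
        for cluster in pk.build_clusters(by_tx[tid], min_reads=params.min_reads):
            sites.extend(pk.call_binding_sites(cluster, profile, tx_by_id[tid], params))
    return sites
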