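import pytest

from triosv.synthetic_trio import TrioConfig, default_sv_counts, simulate_trio


@pytest.fixture(scope="session")
def small_trio():
    """A small but complete trio: 2 x 120 kb, 4 events/type/terminal branch,
    with the retro-inserted gene copy planted."""
    cfg = TrioConfig(
        seed=7,
        n_chroms=2,
        chrom_length=120_000,
        sv_counts=default_sv_counts(4),
        retrocopy=True,
    )
    return simulate_trio(cfg)
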