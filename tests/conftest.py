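import pytest

from primerscope import FixtureSpec, generate_dataset, parse_genbank


@pytest.fixture(scope="session")
def small_dataset():
    """A small clean synthetic cohort (4 phyla x 6 records, light noise)."""
    spec = FixtureSpec(
        seed=11,
        n_per_phylum={"Alphaphora": 6, "Betazoa": 6, "Gammatoda": 6, "Deltaria": 6},
        fwd_site_sub_prob=0.03,
        rev_site_sub_prob=0.03,
    )
    return generate_dataset(spec)


@pytest.fixture(scope="session")
def small_records(small_dataset):
    return parse_genbank(small_dataset.genbank_text)
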