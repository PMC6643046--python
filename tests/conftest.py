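import pytest

from stoichlab import Construct, DnaFragment


@pytest.fixture
def znf():
    """Untagged zinc-finger array construct, 55 kD monomer."""
    return Construct(name="ZnF", monomer_mw=55.0, expression_system="IVE")


@pytest.fixture
def eyfp_znf():
    """eYFP-tagged truncated zinc-finger array, 77 kD monomer."""
    return Construct(
        name="eYFP-ZnF-1-11",
        monomer_mw=77.0,
        tags=("eYFP",),
        expression_system="bacterial_SN",
        pi=8.84,
    )


@pytest.fixture
def single_75():
    return DnaFragment(name="single-75", length=75, n_sites=1)


@pytest.fixture
def single_273():
    return DnaFragment(name="single-273", length=273, n_sites=1)


@pytest.fixture
def tandem_bamhi():
    """232-bp two-site fragment with an internal restriction site (75 + 157)."""
    return DnaFragment(
        name="tandem-BamHI",
        length=232,
        n_sites=2,
        has_internal_cut_site=True,
        cut_products=(75, 157),
    )
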