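import hypothesis
import pytest

from dropdel import AssayModel, LibraryDesign, ScreenConfig, build_scheme

hypothesis.settings.register_profile(
    "suite", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("suite")


@pytest.fixture(scope="session")
def design9():
    """2 split-and-pool cycles x 3 building blocks = 9 members."""
    return LibraryDesign.from_lists(
        [["amine-1", "amine-2", "amine-3"], ["acid-1", "acid-2", "acid-3"]],
        name="demo9",
    )


@pytest.fixture(scope="session")
def scheme9(design9):
    return build_scheme(design9, codon_length=4, min_hamming=3, seed=7)


@pytest.fixture(scope="session")
def design2000():
    """2-cycle 40 x 50 design used for pipeline-scale simulations."""
    return LibraryDesign.from_lists(
        [[f"a{i}" for i in range(40)], [f"b{i}" for i in range(50)]],
        name="sim2000",
    )


@pytest.fixture
def strong_assay():
    """Fully inhibiting actives on a tight fluorogenic baseline."""
    return AssayModel(
        mu_neg=100.0, sigma_neg=8.0, active_members=frozenset(range(5)), effect=1.0
    )


@pytest.fixture
def screen_config():
    return ScreenConfig(bead_occupancy=0.05, window=1000)
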