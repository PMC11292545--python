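import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from pepiso.digest import IsoformCatalog
from pepiso.io_formats import AnalysisThresholds, SampleDesign

settings.register_profile(
    "pepiso",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("pepiso")


@pytest.fixture
def two_isoform_catalog() -> IsoformCatalog:
    """One single-isoform family, one 2-isoform family, one extra singleton."""
    return IsoformCatalog(
        {
            "P1": ("P1",),
            "Q1": ("Q1-1", "Q1-2"),
            "R1": ("R1",),
        }
    )


@pytest.fixture
def small_design() -> SampleDesign:
    return SampleDesign((("s1", "A"), ("s2", "A"), ("s3", "B"), ("s4", "B")))


@pytest.fixture
def fast_thresholds() -> AnalysisThresholds:
    return AnalysisThresholds(permutations=100, seed=0)


def write_tsv(path, text: str) -> str:
    path.write_text(text, encoding="utf-8")
    return str(path)


@pytest.fixture
def area_tsv(tmp_path):
    return write_tsv(
        tmp_path / "areas.tsv",
        "sequence\tmodification\ts1\ts2\n"
        "PEPTIDEK\t\t1.0\t1.0\n"
        "SEQVENCER\tOxidation\t1.0\t1.0\n",
    )


def make_area_table(values: dict[str, list[float]], peptides: list[tuple[str, str]]):
    """Peptide-by-sample DataFrame in the reader's output convention."""
    index = pd.MultiIndex.from_tuples(peptides, names=("sequence", "modification"))
    return pd.DataFrame(values, index=index, dtype=float)
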