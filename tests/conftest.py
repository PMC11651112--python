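import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from crisprecol.incidence import IncidenceMap, StrainAnnotation

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def genus_imap() -> IncidenceMap:
    """Small genus-level incidence map used across density/diversity tests."""
    values = {"a": 1.0, "b": 1.0, "c": 0.0, "d": 0.0}
    return IncidenceMap("genus", values, {g: 1 for g in values})


@pytest.fixture
def strain_table() -> list[StrainAnnotation]:
    return [
        StrainAnnotation("s1", "X", "G", 4),
        StrainAnnotation("s2", "X", "G", 4),
        StrainAnnotation("s3", "X", "G", 1),
        StrainAnnotation("s4", "Y", "G", 4),
        StrainAnnotation("s5", "Y", "G", 0),
        StrainAnnotation("s6", "Z", "H", 3),
        StrainAnnotation("s7", "Z", "H", 2),
    ]


@pytest.fixture
def small_counts() -> pd.DataFrame:
    """4 genera x 3 samples, genus 'a' present everywhere."""
    return pd.DataFrame(
        {
            "S1": [5, 3, 0, 2],
            "S2": [7, 0, 1, 4],
            "S3": [2, 6, 8, 0],
        },
        index=pd.Index(["a", "b", "c", "d"], name="genus"),
    )
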