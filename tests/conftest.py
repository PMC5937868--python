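import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from helm_assess.core import Dafor, LifeForm, PlotObservation, TaxonRecord, TransectSurvey


def make_survey(taxon_categories, lake_id="LAKE", transect_id="T1", year=2014, c_max_m=5.0):
    """Transect with one plot observation per (taxon_id, Dafor) pair."""
    obs = [
        PlotObservation(lake_id=lake_id, transect_id=transect_id, year=year,
                        depth_zone="0-1", plot_index=i + 1, taxon_id=tid, abundance=cat)
        for i, (tid, cat) in enumerate(taxon_categories)
    ]
    return TransectSurvey(lake_id=lake_id, transect_id=transect_id, year=year,
                          observations=obs, c_max_m=c_max_m)


@pytest.fixture
def simple_taxa():
    """Small scored taxa table: two submerged low-rank and two emergent
    high-rank taxa, one of them scoreable only through Ellenberg N."""
    return {
        "elo1": TaxonRecord("elo1", "Elodeid one", LifeForm.ELODEID, ltr=6.0),
        "elo2": TaxonRecord("elo2", "Elodeid two", LifeForm.ELODEID, ltr=4.0),
        "hel1": TaxonRecord("hel1", "Helophyte one", LifeForm.HELOPHYTE, ltr=9.0),
        "hel2": TaxonRecord("hel2", "Helophyte two", LifeForm.HELOPHYTE, ltr=None, ellenberg_n=5.0),
        "moss": TaxonRecord("moss", "Unscored moss", LifeForm.OTHER),
    }
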