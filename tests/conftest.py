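import sys
from pathlib import Path

import pytest

# the NOAA reference oracle lives beside the acceptance script
sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "scripts"))

from antfield import CampaignDatabase, CivilInstant, GeoPosition  # noqa: E402


TUNISIA = GeoPosition(latitude=34.95, longitude=9.97, utc_offset=1.0)


@pytest.fixture
def db(tmp_path):
    """An empty campaign database in a temporary file."""
    with CampaignDatabase(tmp_path / "campaign.sqlite") as store:
        yield store


@pytest.fixture
def populated_db(db):
    """A small hand-built campaign: 1 experiment, 2 feeders, 2 ants, 3 visits."""
    exp = db.create_experiment(
        name="saltpan-1", date="2015-06-01", time="08:00:00", position=TUNISIA
    )
    f1 = db.add_feeder(exp.id, "north feeder")
    f2 = db.add_feeder(exp.id, "south feeder")
    a1 = db.register_individual(exp.id, "A1", ("red", "blue", "white"))
    a2 = db.register_individual(exp.id, "A2", ("green", "green", "yellow"))
    db.record_visit(a1.id, feeder_id=f1.id, timestamp=CivilInstant(2015, 6, 1, 9, 15, 0))
    db.record_visit(a1.id, feeder_id=f2.id, timestamp=CivilInstant(2015, 6, 1, 11, 40, 30))
    db.record_visit(a2.id, feeder_id=f1.id, timestamp=CivilInstant(2015, 6, 1, 14, 5, 12))
    return db
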