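"""Synthetic campaign generator.

Emulates the field protocol of a mark–resight feeder study: per experiment
a set of feeders is placed, a cohort of individuals is paint-marked with
unique three-dot colour codes, and each individual's feeder visits arrive
as a homogeneous Poisson process within the daily observation window.
Every visit is solar-annotated through the ordinary datastore path, so a
generated file satisfies all store invariants and exercises export and
merge exactly as a hand-entered campaign would.

Defaults portray a Saharan salt-pan setting in early summer — the habitat
of the thermophilic desert ants whose navigation studies motivated the
toolkit: latitudes 33.5–35 °N, longitudes 9–10.5 °E, UTC+1, observations
08:00–18:00 local time, ten marked foragers per experiment making on
average ten feeder visits each.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Tuple, Union

import numpy as np

from .datastore import CampaignDatabase
from .solar import CivilInstant, GeoPosition

__all__ = ["DEFAULT_PALETTE", "CampaignSpec", "generate_campaign"]

DEFAULT_PALETTE = ("red", "blue", "green", "yellow", "white", "orange", "pink", "silver")


@dataclass(frozen=True)
class CampaignSpec:
    """Parameters of one synthetic campaign.

    ``visits_per_individual`` is the mean of the Poisson visit count;
    ``day_window`` is the observation window in local clock hours
    (start < end); coordinate ranges are in decimal degrees.  Identical
    spec + seed reproduces the campaign file byte-for-byte.
    """

    n_experiments: int = 3
    feeders_per_experiment: int = 2
    individuals_per_experiment: int = 10
    visits_per_individual: float = 10.0
    day_window: Tuple[float, float] = (8.0, 18.0)
    latitude_range: Tuple[float, float] = (33.5, 35.0)
    longitude_range: Tuple[float, float] = (9.0, 10.5)
    utc_offset: float = 1.0
    start_date: Tuple[int, int, int] = (2015, 6, 1)
    palette: Tuple[str, ...] = DEFAULT_PALETTE
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_experiments", "feeders_per_experiment", "individuals_per_experiment"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.visits_per_individual < 0:
            raise ValueError("visits_per_individual must be >= 0")
        if not self.day_window[0] < self.day_window[1]:
            raise ValueError("day_window start must precede end")
        if len(self.palette) < 6:
            raise ValueError("palette must offer at least six colors")

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "CampaignSpec":
        data = json.loads(Path(path).read_text())
        for key in ("day_window", "latitude_range", "longitude_range", "start_date", "palette"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def _clock(hours: float) -> Tuple[int, int, int]:
    total = int(round(hours * 3600.0))
    return total // 3600, (total % 3600) // 60, total % 60


def generate_campaign(spec: CampaignSpec, out_path: Union[str, Path]) -> Path:
    """Write a complete synthetic campaign database to ``out_path``.

    Colour codes are ordered triples drawn without replacement from the
    palette's triple space (repeats *within* a triple are allowed, as with
    real paint dots); requesting more individuals than the palette's
    ``len(palette)**3`` triples permit raises a capacity error.  Visit
    counts are Poisson(``visits_per_individual``); conditional on the count,
    arrival times are independent uniforms over the day window — the
    standard construction of a homogeneous Poisson process.
    """
    n_codes = len(spec.palette) ** 3
    if spec.individuals_per_experiment > n_codes:
        raise ValueError(
            f"cannot mark {spec.individuals_per_experiment} individuals uniquely:"
            f" palette of {len(spec.palette)} colors yields only {n_codes} three-dot codes"
        )
    rng = np.random.default_rng(spec.seed)
    out = Path(out_path)
    if out.exists():
        out.unlink()
    all_codes = list(itertools.product(spec.palette, repeat=3))
    start = spec.day_window[0]
    span = spec.day_window[1] - spec.day_window[0]
    with CampaignDatabase(out) as db:
        for e_idx in range(spec.n_experiments):
            date = _advance_date(spec.start_date, e_idx)
            lat = float(rng.uniform(*spec.latitude_range))
            lon = float(rng.uniform(*spec.longitude_range))
            position = GeoPosition(lat, lon, spec.utc_offset)
            exp = db.create_experiment(
                name=f"experiment-{e_idx + 1}",
                date="%04d-%02d-%02d" % date,
                time="%02d:%02d:%02d" % _clock(start),
                position=position,
                notes=f"synthetic campaign, seed {spec.seed}",
            )
            feeders = [
                db.add_feeder(exp.id, label=f"feeder-{e_idx + 1}-{f + 1}")
                for f in range(spec.feeders_per_experiment)
            ]
            code_idx = rng.choice(n_codes, size=spec.individuals_per_experiment, replace=False)
            for i_idx in range(spec.individuals_per_experiment):
                individual = db.register_individual(
                    exp.id,
                    name_or_number=f"ant-{i_idx + 1}",
                    color_code=all_codes[int(code_idx[i_idx])],
                )
                n_visits = int(rng.poisson(spec.visits_per_individual))
                arrival_hours = np.sort(rng.uniform(start, start + span, size=n_visits))
                for hours in arrival_hours:
                    h, m, s = _clock(float(hours))
                    feeder = feeders[int(rng.integers(len(feeders)))] if feeders else None
                    db.record_visit(
                        individual.id,
                        feeder_id=feeder.id if feeder else None,
                        timestamp=CivilInstant(*date, h, m, s),
                    )
    return out


def _advance_date(start: Tuple[int, int, int], days: int) -> Tuple[int, int, int]:
    from datetime import date as _d, timedelta

    d = _d(*start) + timedelta(days=days)
    return d.year, d.month, d.day
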