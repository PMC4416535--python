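"""Plain-text application configuration shared by the CLI subcommands."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

from .solar import GeoPosition

__all__ = ["AppConfig", "DEFAULT_PASSPHRASE"]

DEFAULT_PASSPHRASE = "changeme"
_LOG_LEVELS = ("quiet", "info", "debug")


@dataclass
class AppConfig:
    """Default coordinates, the record-deletion security key, and verbosity.

    Round-trips losslessly through a small JSON file, so field crews can
    keep one config per site.
    """

    default_position: Optional[GeoPosition] = None
    passphrase: str = DEFAULT_PASSPHRASE
    log_level: str = "info"

    def __post_init__(self) -> None:
        if self.log_level not in _LOG_LEVELS:
            raise ValueError(f"log_level must be one of {_LOG_LEVELS}, got {self.log_level!r}")

    @classmethod
    def load(cls, path: Union[str, Path]) -> "AppConfig":
        data = json.loads(Path(path).read_text())
        pos = data.get("default_position")
        return cls(
            default_position=GeoPosition(**pos) if pos else None,
            passphrase=data.get("passphrase", DEFAULT_PASSPHRASE),
            log_level=data.get("log_level", "info"),
        )

    def save(self, path: Union[str, Path]) -> None:
        pos = self.default_position
        data = {
            "default_position": (
                {"latitude": pos.latitude, "longitude": pos.longitude, "utc_offset": pos.utc_offset}
                if pos
                else None
            ),
            "passphrase": self.passphrase,
            "log_level": self.log_level,
        }
        Path(path).write_text(json.dumps(data, indent=2) + "\n")
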