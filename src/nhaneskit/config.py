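"""Runtime configuration: cache location, base URL, offline mode, design defaults."""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field, replace
from pathlib import Path

__all__ = ["Config", "load_config", "DEFAULT_BASE_URL"]

#: URL template for raw table downloads; {years} is e.g. "2017-2018".
DEFAULT_BASE_URL = "https://wwwn.cdc.gov/Nchs/Nhanes/{years}/{table}.{ext}"


@dataclass
class Config:
    cache_dir: Path = field(default_factory=lambda: Path.home() / ".cache" / "nhaneskit")
    base_url: str = DEFAULT_BASE_URL
    offline: bool = False
    strata_var: str = "SDMVSTRA"
    psu_var: str = "SDMVPSU"
    weight_var: str = "WTMEC2YR"
    log_level: str = "INFO"

    def with_overrides(self, **kwargs) -> "Config":
        kwargs = {k: v for k, v in kwargs.items() if v is not None}
        if "cache_dir" in kwargs:
            kwargs["cache_dir"] = Path(kwargs["cache_dir"])
        return replace(self, **kwargs)


def load_config(path: str | Path | None = None) -> Config:
    """Load a TOML config file; missing file or keys fall back to defaults."""
    cfg = Config()
    if path is None:
        return cfg
    path = Path(path)
    if not path.exists():
        return cfg
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    design = data.pop("design", {})
    return cfg.with_overrides(
        cache_dir=data.get("cache_dir"),
        base_url=data.get("base_url"),
        offline=data.get("offline"),
        log_level=data.get("log_level"),
        strata_var=design.get("strata_var"),
        psu_var=design.get("psu_var"),
        weight_var=design.get("weight_var"),
    )
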