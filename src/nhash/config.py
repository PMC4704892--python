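"""Profile and run configuration loading.

A hash profile is described in a small YAML (or JSON — YAML is a
superset) file::

    components:
      - [name, 4]
      - [mrn, 4]
      - [dob, 2]
    random_digits: 6

The name ``"csr"`` resolves to the built-in default profile.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import yaml

from .core import CSR_PROFILE, HashProfile
from .errors import NHashError

__all__ = ["load_profile", "RunConfig"]


def load_profile(spec: str | os.PathLike | None) -> HashProfile:
    """Resolve a profile name or config-file path to a :class:`HashProfile`."""
    if spec is None or str(spec).lower() == "csr":
        return CSR_PROFILE
    path = os.fspath(spec)
    if not os.path.exists(path):
        raise NHashError(f"profile {spec!r} is neither 'csr' nor an existing file")
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict) or "components" not in data:
        raise NHashError(f"profile file {path} must define 'components'")
    try:
        components = tuple((str(src), int(n)) for src, n in data["components"])
    except (TypeError, ValueError) as exc:
        raise NHashError(f"bad components in {path}: {exc}") from exc
    return HashProfile(
        components=components,
        random_digits=int(data.get("random_digits", 6)),
    )


@dataclass(frozen=True)
class RunConfig:
    """Resolved settings for one CLI invocation."""

    profile: HashProfile
    registry_path: str | None = None
    input_path: str | None = None
    output_path: str | None = None
    seed: int | None = None
    site: str = "local"
    log_path: str | None = None
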