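"""Dataset serialization and the packaged illustrative dataset.

Datasets travel as self-describing CSV: commented preamble lines carry the
design constants (n, N1, N2), followed by a header and one record per failure
with columns ``index,time,cause,removed``. Times are written with full
``repr`` precision so a write/read round trip is exact.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .model import CensoringScheme, StepStressDataset

__all__ = ["read_dataset", "write_dataset", "load_illustrative_dataset"]

_PREAMBLE_KEYS = ("n", "N1", "N2")


def write_dataset(data: StepStressDataset, path) -> None:
    """Write a dataset as self-describing CSV (deterministic byte-for-byte)."""
    lines = [f"# {k}={getattr(data.scheme, k)}" for k in _PREAMBLE_KEYS]
    lines.append("index,time,cause,removed")
    for i, (t, c, r) in enumerate(
        zip(data.times, data.causes, data.scheme.removals), start=1
    ):
        lines.append(f"{i},{t!r},{c},{r}")
    Path(path).write_text("\n".join(lines) + "\n")


def _parse(text: str, source: str) -> StepStressDataset:
    meta: dict[str, int] = {}
    times: list[float] = []
    causes: list[int] = []
    removals: list[int] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                k, _, v = body.partition("=")
                if k.strip() in _PREAMBLE_KEYS:
                    meta[k.strip()] = int(v)
            continue
        if line.lower().startswith("index,"):
            continue
        parts = line.split(",")
        if len(parts) != 4:
            raise ValueError(f"{source}:{lineno}: expected 4 columns, got {len(parts)}")
        try:
            times.append(float(parts[1]))
            cause = int(parts[2])
            removed = int(parts[3])
        except ValueError as exc:
            raise ValueError(f"{source}:{lineno}: unparseable record: {exc}") from None
        if cause not in (1, 2):
            raise ValueError(f"{source}:{lineno}: cause must be 1 or 2, got {cause}")
        if removed < 0:
            raise ValueError(f"{source}:{lineno}: negative removal count")
        causes.append(cause)
        removals.append(removed)
    missing = [k for k in _PREAMBLE_KEYS if k not in meta]
    if missing:
        raise ValueError(f"{source}: missing preamble keys {missing}")
    scheme = CensoringScheme(
        n=meta["n"], N1=meta["N1"], N2=meta["N2"], removals=tuple(removals)
    )
    return StepStressDataset(scheme=scheme, times=tuple(times), causes=tuple(causes))


def read_dataset(path) -> StepStressDataset:
    """Read and validate a dataset CSV written by :func:`write_dataset`."""
    path = Path(path)
    return _parse(path.read_text(), str(path))


def load_illustrative_dataset() -> StepStressDataset:
    """The packaged illustrative dataset: n=30 units, 10 + 12 failures.

    A simulated step-stress competing-risks sample (true rates 1.0, 1.5, 2.0,
    3.0) with four units withdrawn at the last failure of each stage (the
    stage-end removal convention).
    """
    text = (
        resources.files("stepstress").joinpath("data/illustrative.csv").read_text()
    )
    return _parse(text, "stepstress/data/illustrative.csv")
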