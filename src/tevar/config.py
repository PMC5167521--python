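"""Tunable thresholds for the caller, with a flat key=value config loader.

Every threshold that shapes a call is collected here so a single config
file can reproduce or perturb a run.  Defaults follow the published
method: discordance at four insert-size standard deviations, split reads
kept at >=5 kb separation and MAPQ >= 5, 80% TE overlap for evidence
linking and absence spanning, a 10% internal/flank depth ratio, a read
threshold of coverage/10 (floor 2), and a 20 kb cap on spanned intervals.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path


@dataclass
class DiscoverParams:
    sd_multiplier: float = 4.0       # discordance: |insert| > mean + k*sd
    min_mapq: int = 5                # split-read mapping quality floor
    min_split_distance: int = 5_000  # drop split reads from small indels
    max_span: int = 20_000           # drop spanning evidence from large SVs
    te_overlap_frac: float = 0.8     # read/TE overlap to link evidence to a TE
    span_frac: float = 0.8           # fraction of TE length spanned for absence
    depth_ratio: float = 0.1         # internal depth < 10% of flanks
    flank_bp: int = 2_000            # flank width for the depth comparison
    coverage_divisor: int = 10       # read threshold = coverage / divisor
    min_reads: int = 2               # floor of the read threshold
    min_proper_pairs: int = 1_000    # needed to estimate the insert model
    trim_frac: float = 0.01          # trimmed tails when estimating insert stats
    strict: bool = False             # double thresholds (highly related samples)
    merge_distance: int | None = None  # evidence clustering; None -> mean + k*sd

    def threshold(self, coverage: float) -> int:
        """Minimum supporting reads for a call at this mean coverage."""
        base = max(self.min_reads, int(coverage // self.coverage_divisor)) \
            if coverage > self.coverage_divisor else self.min_reads
        return base * 2 if self.strict else base


@dataclass
class RefineParams:
    merge_distance: int = 100   # bp between per-sample breakpoints to merge
    min_split_reads: int = 1    # relaxed evidence threshold at known sites


def _coerce(value: str, typ) -> object:
    text = value.strip()
    if typ in (int, "int | None", int | None):
        return None if text.lower() in ("none", "") else int(float(text))
    if typ is float:
        return float(text)
    if typ is bool:
        return text.lower() in ("1", "true", "yes", "on")
    return text


def load_config(path: str | Path, *params_objects) -> None:
    """Apply ``key = value`` lines from a flat config file to dataclasses.

    Unknown keys raise; '#' starts a comment.
    """
    fields = {}
    for obj in params_objects:
        for f in dataclasses.fields(obj):
            fields[f.name] = (obj, f.type)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}, line {lineno}: expected key = value")
            key, value = (part.strip() for part in line.split("=", 1))
            if key not in fields:
                raise ValueError(f"{path}, line {lineno}: unknown option {key!r}")
            obj, typ = fields[key]
            typ = {"int": int, "float": float, "bool": bool, "str": str}.get(typ, typ)
            setattr(obj, key, _coerce(value, typ))
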