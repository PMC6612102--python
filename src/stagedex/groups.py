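"""Sample-group vocabulary shared across the pipeline.

Every sample belongs to exactly one of five groups: normal-tissue controls
or one of the four AJCC/TNM parent stages (substages A/B/C are collapsed
into the parent stage upstream).
"""

from __future__ import annotations

CONTROL = "control"
STAGES: tuple[str, ...] = ("I", "II", "III", "IV")
GROUPS: tuple[str, ...] = (CONTROL,) + STAGES

#: Numeric encoding of the ordered progression used by the numeric-stage
#: linear model: control=0, I=1, ..., IV=4.
GROUP_CODES: dict[str, int] = {g: i for i, g in enumerate(GROUPS)}


def validate_group(label: str) -> str:
    if label not in GROUP_CODES:
        raise ValueError(f"unknown sample group label: {label!r}; expected one of {GROUPS}")
    return label
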