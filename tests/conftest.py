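import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from scanopt import SessionTimeline, default_ethogram

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ethogram():
    return default_ethogram()


def build_timeline(
    bouts_by_animal: dict[str, list[tuple[float, float, str]]],
    duration_s: float,
    visibility: dict[str, list[tuple[float, float, bool]]] | None = None,
    session_id: str = "s1",
    **meta,
) -> SessionTimeline:
    """Hand-build a timeline from per-animal (start, end, behavior) triples."""
    bout_rows = [
        {"animal_id": a, "behavior": b, "start_s": s, "end_s": e}
        for a, bouts in bouts_by_animal.items()
        for (s, e, b) in bouts
    ]
    if visibility is None:
        vis_rows = [
            {"animal_id": a, "start_s": 0.0, "end_s": duration_s, "visible": True}
            for a in bouts_by_animal
        ]
    else:
        vis_rows = [
            {"animal_id": a, "start_s": s, "end_s": e, "visible": v}
            for a, spans in visibility.items()
            for (s, e, v) in spans
        ]
    return SessionTimeline(
        session_id=session_id,
        duration_s=duration_s,
        animals=list(bouts_by_animal),
        bouts=pd.DataFrame(bout_rows),
        visibility=pd.DataFrame(vis_rows),
        **meta,
    )


@pytest.fixture
def walker_rester():
    """One animal walking then resting over a 120-s session, fully visible."""
    return build_timeline({"a1": [(0.0, 60.0, "Walking"), (60.0, 120.0, "Resting")]}, 120.0)
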