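from datetime import datetime

from ohca_coverage.synth_city import EventRecord


def make_event(**kw) -> EventRecord:
    base = dict(
        event_id="X", location=(0.0, 0.0),
        call_datetime=datetime(2020, 1, 1, 12, 0), age=60.0, sex="male",
        traumatic=False, response_time_s=700.0, dispatch_time_s=400.0,
        bystander_cpr="yes", shockable=False, death=True,
        cpr_duration_s=1800.0, complete=True,
    )
    base.update(kw)
    return EventRecord(**base)
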