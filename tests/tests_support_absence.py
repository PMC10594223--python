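"""Hand-built fixture: long absence episodes concentrated in one arm.

Used to check the direction of the friction-cost vs human-capital gap:
only episodes longer than the friction period (60 working days) create
a difference between the two valuations, so concentrating such episodes
in the twice-weekly arm must raise that arm's costs more under the
human-capital approach.
"""

import numpy as np
import pandas as pd

from trialcea.datasets import LONG_COLUMNS, TrialDataset


def build_absence_concentrated_trial(n_per_arm: int = 10) -> TrialDataset:
    rows_b, rows_l = [], []
    for arm, episode_days in (("twice", 100), ("once", 10)):
        for i in range(n_per_arm):
            pid = f"{arm}{i:02d}"
            rows_b.append({
                "id": pid, "frequency_arm": arm,
                "therapy": "CBT" if i % 2 == 0 else "IPT", "site": 1,
                "severity_stratum": "high", "age": 40, "gender": "male",
                "education": 1, "employed": 1, "hours_per_day": 8.0,
                "sessions_attended": 16,
            })
            # one episode split over the first two recall periods
            per_period = {3: episode_days / 2, 6: episode_days / 2, 9: 0, 12: 0}
            for m in (0, 3, 6, 9, 12):
                rows_l.append({
                    "id": pid, "month": m, "bdi": 25, "utility": 0.7,
                    "pfs": 60, "sfs": 55, "gp_visits": 0,
                    "psychiatrist_visits": 0, "psychologist_visits": 0,
                    "psych_hospital_days": 0, "antidepressant_ddd": 0,
                    "informal_care_hours": 0,
                    "absence_days": per_period.get(m, 0) if m else 0,
                    "absence_episode_id": f"{pid}-e1" if m in (3, 6) else None,
                    "days_with_complaints": 0, "efficiency": 1.0,
                    "unpaid_hours_lost": 0,
                })
    return TrialDataset(baseline=pd.DataFrame(rows_b),
                        long=pd.DataFrame(rows_l)[LONG_COLUMNS])
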