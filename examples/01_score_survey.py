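"""Score survey exercise records into weekly MET-minute phenotypes.

Each reported activity contributes MET value x sessions/week x
minutes/session; activities flagged as obligatory, transport-only, or
seasonal are excluded.  The scorer also splits the total along three
axes: team vs solitary, competitive vs non-competitive, and externally
vs internally paced.
"""

from exped import ExerciseRecord, load_activity_table, score_participant

table = load_activity_table()          # bundled activity classification

records = [
    ExerciseRecord("anna", "soccer", times_per_week=2, minutes_per_session=90),
    ExerciseRecord("anna", "jogging", times_per_week=1, minutes_per_session=30),
    # cycling to work is transport, not voluntary exercise
    ExerciseRecord("anna", "tour_cycling", times_per_week=5,
                   minutes_per_session=20, transport_flag=True),
]

vec = score_participant(records, table)
print(f"total weekly MET-minutes : {vec.total_metmin:.0f}")
print(f"  team / solitary        : {vec.team_metmin:.0f} / {vec.solitary_metmin:.0f}")
print(f"  competitive / not      : {vec.competitive_metmin:.0f} / {vec.noncompetitive_metmin:.0f}")
print(f"  external / internal    : {vec.external_metmin:.0f} / {vec.internal_metmin:.0f}")
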