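"""Published reference tabulations for the Greater Bangkok winter haze record
(season years 2017-2022).

These are fixed printed inputs, not computed here: the duration-frequency
distribution of the 38 identified haze episodes by meteorological type, the
clean/episodic CO-normalized ratio means for the 13 episodes screened as
potentially secondary-aerosol affected, and the count of episodes with a
biomass-burning contribution. They exercise the tabulation and screening
stages on the real study's numbers and anchor the worked examples in the
documentation.
"""

from __future__ import annotations

#: (duration days, episode count, counts by type I/II/III/IV, cv of daily PM2.5)
DURATION_FREQUENCY_ROWS: list[tuple[int, int, tuple[int, int, int, int], float]] = [
    (1, 11, (0, 4, 0, 7), 0.10),
    (2, 7, (0, 5, 2, 0), 0.16),
    (3, 3, (0, 2, 0, 1), 0.10),
    (4, 3, (0, 1, 2, 0), 0.12),
    (5, 2, (0, 2, 0, 0), 0.21),
    (6, 2, (1, 0, 1, 0), 0.10),
    (7, 2, (1, 1, 0, 0), 0.09),
    (8, 2, (2, 0, 0, 0), 0.15),
    (10, 2, (0, 0, 2, 0), 0.16),
    (11, 1, (0, 0, 1, 0), 0.29),
    (13, 2, (0, 0, 2, 0), 0.21),
    (14, 1, (0, 0, 1, 0), 0.25),
]

#: Clean vs episodic daytime ratio means for the 13 screened episodes:
#: (episode id, type, clean/episodic PM2.5/CO, clean/episodic NOx/CO,
#:  clean/episodic SO2/CO); None marks an unavailable SO2 record.
SECONDARY_RATIO_ROWS: list[tuple[int, str, float, float, float, float,
                                 float | None, float | None]] = [
    (1, "I", 56.5, 57.2, 55.9, 53.1, 2.9, 2.5),
    (6, "II", 56.5, 63.6, 55.9, 54.5, 2.9, 2.7),
    (7, "IV", 56.5, 66.3, 55.9, 50.6, 2.9, 3.6),
    (11, "IV", 56.5, 83.8, 55.9, 52.2, 2.9, 2.9),
    (12, "II", 66.4, 79.1, 59.9, 54.5, 2.7, 4.2),
    (16, "III", 66.4, 83.4, 59.9, 50.61, 2.7, 2.5),
    (21, "III", 52.8, 57.1, 50.3, 48.6, 1.7, 1.8),
    (22, "II", 52.8, 63.7, 50.3, 44.8, 1.7, 1.7),
    (25, "IV", 56.9, 67.2, 57.8, 46.9, 1.8, 0.9),
    (26, "II", 56.9, 61.6, 57.8, 48.6, 1.8, 1.5),
    (27, "I", 56.9, 66.3, 57.8, 38.1, 1.8, 2.3),
    (37, "II", 47.0, 51.7, 36.7, 31.2, 2.1, None),
    (38, "II", 47.0, 56.2, 36.7, 35.9, 2.1, None),
]

#: Headline counts of the published record.
TOTAL_EPISODES = 38
TOTAL_HAZE_DAYS = 159
BIOMASS_AFFECTED_EPISODES = 19


def reference_episodes():
    """Reconstruct episode objects matching the published duration-frequency
    distribution (arbitrary non-overlapping dates; durations, type labels and
    per-duration cv as printed). Returns (episodes, types)."""
    from datetime import date, timedelta

    from .haze_detection import HazeEpisode

    episodes = []
    types: dict[int, str] = {}
    cursor = date(2017, 1, 1)
    eid = 0
    for duration, count, by_type, cv in DURATION_FREQUENCY_ROWS:
        labels = [t for t, n in zip(("I", "II", "III", "IV"), by_type)
                  for _ in range(n)]
        assert len(labels) == count
        for label in labels:
            eid += 1
            ep = HazeEpisode(eid, cursor, cursor + timedelta(days=duration - 1))
            ep.cv_pm25 = cv
            ep.type_label = label
            episodes.append(ep)
            types[eid] = label
            cursor += timedelta(days=duration + 5)
    return episodes, types
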