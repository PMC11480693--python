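"""Pinned game constants.

Every geometric tolerance, band and timing that the game mechanics need is
fixed here in one table so that all downstream numbers are reproducible.
Clinically motivated values (the 4.5 s hold, the 25 s inactivity timeout,
the 5 s collision-restart rule, the task counts 14/12/16/16 and the 3
failed-effort allowance) follow the published protocol; the purely
geometric tolerances are package conventions.
"""

import json

GAMES = ("AC", "BF", "CP", "IJ")

MAX_FAILED_EFFORTS = 3  # per challenge instance (IJ island / BF task)

GAME_CONSTANTS = {
    "AC": {
        "n_tasks": 14,
        "task_duration_s": 5.0,      # 4 s fall + 1 s reset gap
        "fall_duration_s": 4.0,
        "capture_window_s": 0.5,     # carriage must sit under the apple here
        "catch_band": 0.08,          # |carriage - apple| tolerance
        "smooth_window_s": 0.1,      # moving average on the carriage position
    },
    "BF": {
        "n_tasks": 12,
        "task_duration_s": 7.0,
        "obstacle_window_s": (1.8, 3.2),
        "smiley_time_s": 3.7,
        "smiley_window_s": 0.25,     # half-window scanned for the min distance
        "smiley_band": 0.06,         # altitude tolerance for collection
        "collision_restart_s": 5.0,  # uncorrected collision -> restart
        # obstacle top altitude and smiley altitude per obstacle class
        "obstacle_heights": {"low": 0.15, "intermediate": 0.35, "high": 0.55},
        "smiley_offset": 0.20,       # smiley sits this far above the obstacle
    },
    "CP": {
        "n_tasks": 16,
        "task_duration_s": 25.0,     # equals the inactivity timeout
        "timeout_s": 25.0,
        "hold_duration_s": 4.5,      # continuous in-band time for success
        "band_low": (0.15, 0.45),
        "band_high": (0.55, 0.85),
        "relax_threshold": 0.10,     # pressure below this counts as released
    },
    "IJ": {
        "n_tasks": 16,
        "task_duration_s": 8.0,
        "targets": {"low": 0.30, "middle": 0.50, "high": 0.70},
        "target_band": 0.08,         # |released - target| tolerance
        "release_fraction": 0.2,     # drop below this x rolling peak ...
        "release_window_s": 0.1,     # ... within this long = a release
        "onset_threshold": 0.10,     # charge pressure that starts an attempt
        "direction_deadband": 0.05,  # |pL-pR| below this = straight
        "max_failed": MAX_FAILED_EFFORTS,
    },
}

GAME_MAX_SCORE = {"AC": 14, "BF": 12, "CP": 16, "IJ": 16}


def game_constants_json() -> str:
    """Export the constants table as a JSON document for audit."""
    return json.dumps(
        {"max_failed_efforts": MAX_FAILED_EFFORTS,
         "max_scores": GAME_MAX_SCORE,
         "games": GAME_CONSTANTS},
        indent=1, sort_keys=True)
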