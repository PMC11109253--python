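"""Canonical file formats for session logs and maze configurations.

Session logs are flat CSV, one row per trial, with a JSON sidecar (same
path, ``.json`` extension) carrying the maze definition and generator
provenance (seeds, parameters).  Grid coordinates follow the task's
convention in files — rows and columns 1-4, row 1 at the top — and are
converted to 0-based row-major cell indices internally.  Directions are
letters (L/F/R relative, N/E/S/W absolute).  Reading validates the schema
and raises :class:`SessionFormatError` naming the offending row and field.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .maze_env import (ABS_NAMES, REL_NAMES, Action, GameRecord, MazeConfig,
                       Pose, TrialRecord)

SESSION_COLUMNS = [
    "participant", "half", "game", "trial", "row", "col", "orientation",
    "action", "move_dir", "roar", "report_td", "report_row", "report_col",
    "conf_td", "conf_grid", "missed_action", "missed_report_td",
    "missed_report_gr", "termination", "trial_limit", "n_explored",
    "n_listen", "score",
]


class SessionFormatError(ValueError):
    pass


# -- maze configs ------------------------------------------------------------


def write_maze(maze: MazeConfig, path) -> None:
    """Write a maze config as JSON (dimensions, alpha, explicit tiger-edge
    list as cell pairs); the round trip through read_maze is lossless."""
    Path(path).write_text(json.dumps(maze.to_dict(), indent=1) + "\n")


def read_maze(path) -> MazeConfig:
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
    return MazeConfig.from_dict(data)


# -- session logs ------------------------------------------------------------


def _cell_to_rowcol(cell: int, maze: MazeConfig) -> tuple:
    return cell // maze.n_cols + 1, cell % maze.n_cols + 1


def _rowcol_to_cell(row: int, col: int, maze: MazeConfig) -> int:
    return (row - 1) * maze.n_cols + (col - 1)


def sessions_to_frame(cohort: dict, maze: MazeConfig) -> pd.DataFrame:
    """Flatten a pid -> list[GameRecord] mapping into the canonical trial
    table."""
    rows = []
    for pid, sessions in cohort.items():
        for game in sessions:
            for t, trial in enumerate(game.trials):
                r, c = _cell_to_rowcol(trial.pose.grid, maze)
                rep_row = rep_col = None
                if trial.report_grid is not None:
                    rep_row, rep_col = _cell_to_rowcol(trial.report_grid, maze)
                rows.append({
                    "participant": pid,
                    "half": game.half,
                    "game": game.game_index,
                    "trial": t + 1,
                    "row": r, "col": c,
                    "orientation": ABS_NAMES[trial.pose.orientation],
                    "action": trial.action.kind if trial.action else None,
                    "move_dir": (REL_NAMES[trial.action.direction]
                                 if trial.action and trial.action.kind == "move"
                                 else None),
                    "roar": REL_NAMES[trial.roar] if trial.roar is not None else None,
                    "report_td": (REL_NAMES[trial.report_td]
                                  if trial.report_td is not None else None),
                    "report_row": rep_row, "report_col": rep_col,
                    "conf_td": (None if trial.conf_td is None
                                else ("high" if trial.conf_td else "low")),
                    "conf_grid": (None if trial.conf_grid is None
                                  else ("high" if trial.conf_grid else "low")),
                    "missed_action": trial.missed_action,
                    "missed_report_td": trial.missed_report_td,
                    "missed_report_gr": trial.missed_report_gr,
                    "termination": game.termination,
                    "trial_limit": game.trial_limit,
                    "n_explored": game.n_explored,
                    "n_listen": game.n_listen,
                    "score": game.score,
                })
    return pd.DataFrame(rows, columns=SESSION_COLUMNS)


def write_sessions(cohort, path, maze: MazeConfig,
                   provenance: Optional[dict] = None) -> None:
    """Write session logs as CSV plus a JSON sidecar holding the maze and
    provenance (seeds, parameters, whatever the caller records)."""
    if not isinstance(cohort, dict):
        cohort = {p.participant_id: p.sessions for p in cohort}
    path = Path(path)
    frame = sessions_to_frame(cohort, maze)
    frame.to_csv(path, index=False)
    sidecar = {"maze": maze.to_dict(), "provenance": provenance or {}}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1) + "\n")


def _fail(row_no, field, msg) -> None:
    raise SessionFormatError(f"row {row_no}, field {field!r}: {msg}")


def read_sessions(path):
    """Read session logs written by :func:`write_sessions`.

    Returns ``(cohort, maze, provenance)`` with cohort a pid ->
    list[GameRecord] dict.  The write/read round trip is lossless."""
    path = Path(path)
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise SessionFormatError(f"missing maze sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    maze = MazeConfig.from_dict(sidecar["maze"])
    frame = pd.read_csv(path)
    missing = [c for c in SESSION_COLUMNS if c not in frame.columns]
    if missing:
        raise SessionFormatError(f"missing columns: {missing}")

    rel_code = {ch: i for i, ch in enumerate(REL_NAMES)}
    abs_code = {ch: i for i, ch in enumerate(ABS_NAMES)}

    cohort: dict = {}
    grouped = frame.groupby(["participant", "game"], sort=True)
    for (pid, game_idx), gdf in grouped:
        gdf = gdf.sort_index()
        trials = []
        expected_trial = 1
        for row_no, row in gdf.iterrows():
            if int(row["trial"]) != expected_trial:
                _fail(row_no, "trial", f"expected trial {expected_trial}, "
                      f"got {row['trial']} (indices must be 1,2,... per game)")
            expected_trial += 1
            r, c = int(row["row"]), int(row["col"])
            if not (1 <= r <= maze.n_rows and 1 <= c <= maze.n_cols):
                _fail(row_no, "row", f"coordinates ({r},{c}) outside the maze")
            if row["orientation"] not in abs_code:
                _fail(row_no, "orientation", f"unknown value {row['orientation']!r}")
            pose = Pose(_rowcol_to_cell(r, c, maze), abs_code[row["orientation"]])

            missed_action = bool(row["missed_action"])
            action_val = row["action"] if not pd.isna(row["action"]) else None
            roar_val = row["roar"] if not pd.isna(row["roar"]) else None
            if missed_action:
                if action_val is not None:
                    _fail(row_no, "action", "missed trial carries an action")
                action = None
            elif action_val == "listen":
                if roar_val is None:
                    _fail(row_no, "roar", "Listen trial with null roar")
                action = Action("listen")
            elif action_val == "move":
                if pd.isna(row["move_dir"]):
                    _fail(row_no, "move_dir", "Move trial without a direction")
                if roar_val is not None:
                    _fail(row_no, "roar", "Move trial carries a roar")
                action = Action("move", rel_code[row["move_dir"]])
            else:
                _fail(row_no, "action", f"unknown action {action_val!r}")

            report_grid = None
            if not pd.isna(row["report_row"]):
                rr, rc = int(row["report_row"]), int(row["report_col"])
                if not (1 <= rr <= maze.n_rows and 1 <= rc <= maze.n_cols):
                    _fail(row_no, "report_row", "reported cell outside the maze")
                report_grid = _rowcol_to_cell(rr, rc, maze)
            report_td = None
            if not pd.isna(row["report_td"]):
                if row["report_td"] not in rel_code or row["report_td"] == "B":
                    _fail(row_no, "report_td", f"invalid direction {row['report_td']!r}")
                report_td = rel_code[row["report_td"]]

            def _conf(field):
                v = row[field]
                if pd.isna(v):
                    return None
                if v not in ("high", "low"):
                    _fail(row_no, field, f"invalid confidence {v!r}")
                return v == "high"

            trials.append(TrialRecord(
                pose=pose, action=action,
                roar=rel_code[roar_val] if roar_val is not None else None,
                report_td=report_td, report_grid=report_grid,
                conf_td=_conf("conf_td"), conf_grid=_conf("conf_grid"),
                missed_action=missed_action,
                missed_report_td=bool(row["missed_report_td"]),
                missed_report_gr=bool(row["missed_report_gr"])))
        first = gdf.iloc[0]
        record = GameRecord(
            trials=trials,
            termination=None if pd.isna(first["termination"]) else str(first["termination"]),
            trial_limit=int(first["trial_limit"]),
            n_explored=int(first["n_explored"]),
            n_listen=int(first["n_listen"]),
            score=None if pd.isna(first["score"]) else int(first["score"]),
            game_index=int(game_idx),
            half=str(first["half"]))
        cohort.setdefault(str(pid), []).append(record)
    return cohort, maze, sidecar.get("provenance", {})
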