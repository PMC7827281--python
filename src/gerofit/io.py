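"""File formats: line-oriented frame streams and session-result CSV.

Frame-stream format (text, one frame per line)::

    # gerofit-stream v1 rate=30
    <timestamp> JOINT x y z JOINT x y z ...   (all 25 joints, meters)

Coordinates are written with 6 decimal places; write∘read is the identity
at that precision.  Session results use the same shape as the study's
deposited table — one row per participant × exercise × session with the
average achievement angle — with angles formatted to exactly 5 decimal
places.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .assessment import SessionRecord
from .errors import FormatError
from .skeleton import N_JOINTS, FrameStream, JointId, SkeletalFrame

STREAM_FORMAT_VERSION = 1
STREAM_HEADER_PREFIX = "# gerofit-stream"
COORD_DECIMALS = 6
SESSION_CSV_COLUMNS = [
    "participant_id", "age", "gender", "exercise_id", "session", "average_angle",
]


def write_frame_stream(stream: FrameStream, path: "str | Path") -> None:
    with open(path, "w") as fh:
        fh.write(
            f"{STREAM_HEADER_PREFIX} v{STREAM_FORMAT_VERSION} "
            f"rate={stream.nominal_rate:g}\n"
        )
        for frame in stream:
            parts = [f"{frame.timestamp:.6f}"]
            for j in JointId:
                x, y, z = frame.positions[j]
                parts.append(f"{j.name} {x:.6f} {y:.6f} {z:.6f}")
            fh.write(" ".join(parts) + "\n")


def read_frame_stream(path: "str | Path") -> FrameStream:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith(STREAM_HEADER_PREFIX):
            raise FormatError(f"{path}: missing stream header line")
        tokens = header.split()
        try:
            version = int(tokens[2].lstrip("v"))
            rate = float(dict(t.split("=") for t in tokens[3:])["rate"])
        except (IndexError, KeyError, ValueError) as exc:
            raise FormatError(f"{path}: malformed header {header!r}") from exc
        if version != STREAM_FORMAT_VERSION:
            raise FormatError(f"{path}: unsupported stream version {version}")

        frames = []
        for lineno, line in enumerate(fh, start=2):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 1 + 4 * N_JOINTS:
                n_joints = (len(fields) - 1) // 4
                raise FormatError(
                    f"{path}: line {lineno}: expected {N_JOINTS} joints, "
                    f"found {n_joints}"
                )
            try:
                ts = float(fields[0])
                positions = np.empty((N_JOINTS, 3))
                for i in range(N_JOINTS):
                    name, *xyz = fields[1 + 4 * i : 5 + 4 * i]
                    positions[JointId[name]] = [float(v) for v in xyz]
            except (KeyError, ValueError) as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
            frames.append(SkeletalFrame(ts, positions))
    return FrameStream(frames, nominal_rate=rate)


def write_session_csv(records: list[SessionRecord], path: "str | Path") -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(SESSION_CSV_COLUMNS)
        for r in records:
            writer.writerow(
                [r.participant_id, r.age, r.gender, r.exercise_id,
                 r.session_index, f"{r.average_angle:.5f}"]
            )


def read_session_csv(path: "str | Path") -> list[SessionRecord]:
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in SESSION_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    return [
        SessionRecord(
            participant_id=str(row.participant_id),
            age=int(row.age),
            gender=str(row.gender),
            exercise_id=str(row.exercise_id),
            session_index=int(row.session),
            average_angle=float(row.average_angle),
        )
        for row in df.itertuples()
    ]
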