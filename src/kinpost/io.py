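"""Plain-text artifact formats: TAC tables and posterior-sample tables.

TAC tables are tab-separated with columns ``tac_id, frame_index, t_start_s,
t_end_s, value`` (long format; a single TAC simply has one id).  Posterior
tables carry ``draw_index, DVR, k2_per_min, R1`` with ``# key: value``
header metadata.  Everything round-trips through pandas.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .mcmc import PosteriorSamples
from .simulator import FrameSchedule, Tac, build_frame_schedule

__all__ = [
    "write_tac_table",
    "read_tac_table",
    "write_posterior_table",
    "read_posterior_table",
]


def write_tac_table(tacs: list[Tac], path: str | Path,
                    sigmas: list[float] | None = None) -> None:
    rows = []
    for tid, tac in enumerate(tacs):
        starts = tac.schedule.frame_start_times
        ends = tac.schedule.frame_end_times
        for n in range(tac.schedule.n_frames):
            rows.append((tid, n, starts[n], ends[n], tac.values[n]))
    df = pd.DataFrame(
        rows, columns=["tac_id", "frame_index", "t_start_s", "t_end_s", "value"]
    )
    with open(path, "w") as fh:
        if sigmas is not None:
            fh.write("# sigma_per_tac: " + ",".join(f"{s:.8e}" for s in sigmas)
                     + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tac_table(path: str | Path) -> tuple[list[Tac], list[float] | None]:
    sigmas = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# sigma_per_tac:"):
            sigmas = [float(v) for v in first.split(":", 1)[1].split(",")]
            df = pd.read_csv(fh, sep="\t")
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t", comment="#")
    tacs = []
    for i, (tid, grp) in enumerate(df.groupby("tac_id", sort=True)):
        grp = grp.sort_values("frame_index")
        schedule = FrameSchedule(frame_end_times=grp["t_end_s"].to_numpy())
        sigma = sigmas[i] if sigmas is not None else None
        tacs.append(Tac(values=grp["value"].to_numpy(), schedule=schedule,
                        noise_sigma=sigma))
    return tacs, sigmas


def write_posterior_table(post: PosteriorSamples, path: str | Path,
                          meta: dict | None = None) -> None:
    df = pd.DataFrame(post.samples, columns=["DVR", "k2_per_min", "R1"])
    df.insert(0, "draw_index", np.arange(post.n))
    header = {"source": post.source}
    if post.acceptance_rate is not None:
        header["acceptance_rate"] = f"{post.acceptance_rate:.4f}"
    header.update({k: str(v) for k, v in (meta or {}).items()})
    with open(path, "w") as fh:
        for key, val in header.items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_posterior_table(path: str | Path) -> PosteriorSamples:
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("# "):
            key, _, val = line[2:].partition(":")
            meta[key.strip()] = val.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t")
    acc = meta.get("acceptance_rate")
    return PosteriorSamples(
        samples=df[["DVR", "k2_per_min", "R1"]].to_numpy(),
        source=meta.get("source", "unknown"),
        acceptance_rate=float(acc) if acc is not None else None,
        provenance=meta,
    )
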