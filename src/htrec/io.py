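"""Standard-format readers/writers: BEDPE junctions, BED copy number,
progeny tallies, event sidecars, and run manifests.

Junction breakends map onto BEDPE strands as R -> "+" (retained sequence at
coordinates <= pos) and L -> "-" (retained at >= pos); coordinates are
0-based half-open per the BEDPE convention.
"""

from __future__ import annotations

import json
import sys
from dataclasses import asdict
from pathlib import Path

import yaml

from .genome import Breakend, CopyNumberProfile, EventRecord, Junction

__all__ = [
    "write_bedpe",
    "read_bedpe",
    "write_cn_bed",
    "read_cn_bed",
    "read_progeny_tsv",
    "write_progeny_tsv",
    "write_events_json",
    "read_events_json",
    "write_manifest",
    "load_yaml_config",
]

_SIDE_TO_STRAND = {"R": "+", "L": "-"}
_STRAND_TO_SIDE = {"+": "R", "-": "L"}

_BEDPE_HEADER = (
    "# BEDPE junctions; strand1/strand2 encode breakend sides: "
    "+ = retained sequence at <= pos (R), - = retained at >= pos (L)\n"
)


def write_bedpe(junctions: list[Junction], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_BEDPE_HEADER)
        for i, j in enumerate(junctions):
            fields = [
                j.a.chrom,
                str(j.a.pos),
                str(j.a.pos + 1),
                j.b.chrom,
                str(j.b.pos),
                str(j.b.pos + 1),
                f"junction_{i}",
                str(j.insert_len),
                _SIDE_TO_STRAND[j.a.side],
                _SIDE_TO_STRAND[j.b.side],
            ]
            fh.write("\t".join(fields) + "\n")


def read_bedpe(path: str | Path) -> list[Junction]:
    junctions = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 10:
                raise ValueError(
                    f"{path}:{lineno}: expected 10 BEDPE columns, got {len(fields)}"
                )
            try:
                c1, s1, _e1, c2, s2, _e2, _name, score, st1, st2 = fields[:10]
                if st1 not in _STRAND_TO_SIDE or st2 not in _STRAND_TO_SIDE:
                    raise ValueError(f"strand must be '+' or '-', got {st1!r}/{st2!r}")
                a = Breakend(c1, int(s1), _STRAND_TO_SIDE[st1])
                b = Breakend(c2, int(s2), _STRAND_TO_SIDE[st2])
                insert_len = int(score) if score not in (".", "") else 0
                junctions.append(Junction(a, b, insert_len))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed BEDPE line: {exc}") from None
    return sorted(set(junctions), key=Junction.sort_key)


def write_cn_bed(profile: CopyNumberProfile, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("# chrom\tstart\tend\tcn (contiguous tiling)\n")
        for start, end, cn in profile.segments:
            fh.write(f"{profile.chrom}\t{start}\t{end}\t{cn}\n")


def read_cn_bed(path: str | Path) -> CopyNumberProfile:
    rows = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            try:
                rows.append((fields[0], int(fields[1]), int(fields[2]), int(fields[3])))
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates or cn") from None
    if not rows:
        raise ValueError(f"{path}: empty copy-number file")
    chrom = rows[0][0]
    if any(r[0] != chrom for r in rows):
        raise ValueError(f"{path}: multiple chromosomes in one profile")
    segments = [(s, e, cn) for _, s, e, cn in rows]
    try:
        return CopyNumberProfile(chrom, tuple(segments))
    except ValueError as exc:
        raise ValueError(f"{path}: invalid copy-number tiling: {exc}") from None


def write_progeny_tsv(counts: dict, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("phenotype_label\tcount\n")
        for label in sorted(counts):
            fh.write(f"{label}\t{counts[label]}\n")


def read_progeny_tsv(path: str | Path) -> dict:
    counts: dict[str, int] = {}
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("phenotype_label\t"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            label, value = fields
            try:
                n = int(value)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer count {value!r}") from None
            if n < 0:
                raise ValueError(f"{path}:{lineno}: negative count {n} for {label!r}")
            counts[label] = counts.get(label, 0) + n
    return counts


def write_events_json(events: list[EventRecord], path: str | Path) -> None:
    payload = [asdict(ev) for ev in events]
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_events_json(path: str | Path) -> list[EventRecord]:
    payload = json.loads(Path(path).read_text())
    out = []
    for item in payload:
        params = {
            k: tuple(v) if isinstance(v, list) else v for k, v in item["params"].items()
        }
        out.append(EventRecord(item["event_class"], params))
    return out


def write_manifest(path: str | Path, seed, config: dict) -> None:
    """Reproducibility manifest: seed, config, and package/python versions."""
    from . import __version__

    manifest = {
        "seed": seed,
        "config": config,
        "htrec_version": __version__,
        "python": sys.version.split()[0],
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")


def load_yaml_config(path: str | Path) -> dict:
    with Path(path).open() as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return data
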