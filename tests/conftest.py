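"""Shared fixtures: small VCF/BED writers and the session-scoped replay run."""

from __future__ import annotations

from pathlib import Path

import pytest

from modyscreen import build_replay_fixture, run_screen


def write_test_vcf(path: Path, samples: list[str], records: list[dict]) -> Path:
    """Write a minimal VCF 4.2.

    Each record dict: chrom, pos, ref, alt (str or list), gts (per-sample GT
    strings like '0/1'), optional dp (per-sample list, scalar, or None for no
    FORMAT/DP), optional info_dp.
    """
    chroms = []
    for r in records:
        if r["chrom"] not in chroms:
            chroms.append(r["chrom"])
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="depth">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="gt">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="dp">',
    ]
    lines += [f"##contig=<ID={c}>" for c in chroms]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples))
    for r in records:
        alt = r["alt"] if isinstance(r["alt"], str) else ",".join(r["alt"])
        dp = r.get("dp", 30)
        info = f"DP={r['info_dp']}" if "info_dp" in r else "."
        if dp is None:
            fmt, cells = "GT", list(r["gts"])
        else:
            dps = dp if isinstance(dp, (list, tuple)) else [dp] * len(samples)
            fmt = "GT:DP"
            cells = [f"{g}:{d}" for g, d in zip(r["gts"], dps)]
        lines.append(
            f"{r['chrom']}\t{r['pos']}\t.\t{r['ref']}\t{alt}\t.\tPASS\t{info}\t{fmt}\t"
            + "\t".join(cells)
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def write_test_bed(path: Path, rows: list[tuple]) -> Path:
    """Write a BED from (chrom, start, end, gene[, subtype]) tuples."""
    path.write_text(
        "\n".join("\t".join(str(x) for x in row) for row in rows) + "\n"
    )
    return path


@pytest.fixture(scope="session")
def replay(tmp_path_factory):
    """The deterministic published-tables replay cohort, built once."""
    outdir = tmp_path_factory.mktemp("replay")
    return build_replay_fixture(outdir)


@pytest.fixture(scope="session")
def replay_screen(replay):
    """Full pipeline result on the replay cohort."""
    return run_screen(
        replay.paths["vcf"],
        replay.paths["phenotypes"],
        replay.paths["panel_bed"],
        replay.paths["annotations"],
    )
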