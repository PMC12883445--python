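"""Report emission: QC summary, run manifest, MultiQC custom-content files."""

from __future__ import annotations

import json
import math
from dataclasses import asdict
from pathlib import Path
from typing import Optional, Sequence

from . import __version__
from .kinship import DEGREE_UNRELATED, KinshipResult, phi_square_table
from .sexinfer import LABEL_AMBIGUOUS, LABEL_UNDEFINED, SexCall
from .xhet import XhetResult


def emit_multiqc(
    xhet_results: Sequence[XhetResult],
    kinship_results: Optional[Sequence[KinshipResult]],
    outdir: str,
) -> list[str]:
    """Write MultiQC custom-content tables mirroring the QC plots.

    Two files: a square kinship matrix rendered as a heatmap and a
    per-sample Xhet table rendered as a bar graph.  Header comments follow
    the custom-content ``# key: value`` grammar; undefined Xhet is an empty
    cell, never 0.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    path = out / "xhet_mqc.tsv"
    with open(path, "w") as fh:
        fh.write("# id: xhetkin_xhet\n")
        fh.write("# section_name: X heterozygosity (Xhet)\n")
        fh.write("# description: Proportion of heterozygous genotypes among "
                 "het + hom-alt genotypes on non-PAR chromosome X. "
                 "XY-like samples score near zero.\n")
        fh.write("# plot_type: bargraph\n")
        fh.write("# pconfig:\n")
        fh.write("#    id: 'xhetkin_xhet_plot'\n")
        fh.write("#    ylab: 'Xhet'\n")
        fh.write("Sample\tXhet\n")
        for r in xhet_results:
            val = "" if r.xhet is None else f"{r.xhet:.6f}"
            fh.write(f"{r.sample_id}\t{val}\n")
    written.append(str(path))

    if kinship_results:
        path = out / "relatedness_mqc.tsv"
        table = phi_square_table(list(kinship_results))
        with open(path, "w") as fh:
            fh.write("# id: xhetkin_relatedness\n")
            fh.write("# section_name: Pairwise kinship\n")
            fh.write("# description: KING-robust kinship coefficients (phi); "
                     "0.5 duplicates, ~0.25 first-degree, ~0 unrelated.\n")
            fh.write("# plot_type: heatmap\n")
            fh.write("\t" + "\t".join(table.columns) + "\n")
            for sid, row in table.iterrows():
                cells = "\t".join(
                    "" if (isinstance(v, float) and math.isnan(v)) else f"{v:.6f}"
                    for v in row
                )
                fh.write(f"{sid}\t{cells}\n")
        written.append(str(path))
    return written


def qc_flags(
    sex_calls: Sequence[SexCall],
    kinship_results: Sequence[KinshipResult],
    expected_sexes: Optional[dict[str, str]] = None,
    expected_pedigree: Optional[dict[str, tuple[Optional[str], Optional[str]]]] = None,
) -> dict[str, list[str]]:
    """Advisory per-sample flags: nothing is ever renamed or dropped.

    Checks inferred sex against recorded metadata (XX vs xx-like) and
    recorded parent-child edges against the kinship degree.  Same-sex
    first-degree pairs are intrinsically indistinguishable here (a
    mother-daughter pair looks like any other first-degree pair), so flags
    name the inconsistency, not a resolution.
    """
    flags: dict[str, list[str]] = {c.sample_id: [] for c in sex_calls}
    label_of = {c.sample_id: c.label for c in sex_calls}
    if expected_sexes:
        want = {"XX": "xx-like", "XY": "xy-like"}
        for sid, sex in expected_sexes.items():
            got = label_of.get(sid)
            if got is None:
                continue
            if got in (LABEL_AMBIGUOUS, LABEL_UNDEFINED):
                flags[sid].append(f"sex-call-{got}")
            elif want.get(sex) and got != want[sex]:
                flags[sid].append(f"sex-mismatch:recorded={sex},inferred={got}")
    if expected_pedigree:
        phi_of = {}
        for r in kinship_results:
            i, j = r.pair
            if i != j:
                phi_of[frozenset((i, j))] = r
        for child, (father, mother) in expected_pedigree.items():
            for parent in (father, mother):
                if parent is None:
                    continue
                r = phi_of.get(frozenset((child, parent)))
                if r is None:
                    continue
                if r.degree in (DEGREE_UNRELATED, "undefined", "second", "third"):
                    for sid in (child, parent):
                        if sid in flags:
                            flags[sid].append(
                                f"pedigree-mismatch:{child}-{parent}"
                                f"(phi={'' if r.phi is None else round(r.phi, 4)})"
                            )
    return flags


def write_summary(
    sex_calls: Sequence[SexCall],
    kinship_results: Sequence[KinshipResult],
    flags: dict[str, list[str]],
    path: str,
    top_k: int = 3,
) -> None:
    """Combined per-sample QC table: xhet, sex label, top kin partners, flags."""
    partners: dict[str, list[tuple[float, str]]] = {}
    for r in kinship_results:
        i, j = r.pair
        if i == j or r.phi is None:
            continue
        partners.setdefault(i, []).append((r.phi, j))
        partners.setdefault(j, []).append((r.phi, i))
    with open(path, "w") as fh:
        fh.write("sample\txhet\tsex_label\ttop_kinship_partners\tflags\n")
        for c in sex_calls:
            x = "" if c.xhet is None else f"{c.xhet:.6f}"
            top = sorted(partners.get(c.sample_id, []), reverse=True)[:top_k]
            top_s = ";".join(f"{sid}:{phi:.4f}" for phi, sid in top)
            fh.write(f"{c.sample_id}\t{x}\t{c.label}\t{top_s}\t"
                     f"{';'.join(flags.get(c.sample_id, [])) or '.'}\n")


def write_manifest(path: str, params: dict) -> None:
    """Machine-readable record of every parameter that shaped the run."""
    payload = {"tool": "xhetkin", "version": __version__, "parameters": params}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
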