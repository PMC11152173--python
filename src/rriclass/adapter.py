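"""Adapter for an external thermodynamic duplex predictor.

The internal additive-energy engine is the default; a user who wants a
full nearest-neighbor/accessibility model can point this adapter at an
external tool. The adapter writes the two window sequences as FASTA,
invokes the tool through a user command template, parses its tabular
output into :class:`~rriclass.duplex.Duplex` values and re-validates
every structural invariant (seed placement, masks, loop limits), so
adapter results are interchangeable with the internal engine downstream.

Command template placeholders: ``{query}`` and ``{target}`` (FASTA paths
for sides 1 and 2), ``{seed_len}``, ``{n}`` (suboptimal count) and
``{out}`` (CSV output path). Expected output: a CSV with columns
``start1,end1,start2,end2,hybridDP,E`` — coordinates 1-based inclusive
within the given sequences, ``hybridDP`` the two-sided dot-bracket
hybrid string (side1 ``(``s, ``&``, side2 ``)``s), ``E`` the energy.
"""

from __future__ import annotations

import csv
import logging
import subprocess
import tempfile
from pathlib import Path

import numpy as np

from .config import Config
from .duplex import Duplex, _seed_annotation, pair_matrices, seed_eligibility, validate_duplex
from .errors import AdapterError

logger = logging.getLogger(__name__)


def parse_hybrid_dp(hybrid: str, start1: int, start2: int):
    """Pairs from a two-sided dot-bracket hybrid string.

    ``start1``/``start2`` are the 0-based offsets of the structure within
    the full sequences. The first '(' on side 1 pairs with the last ')'
    on side 2 (antiparallel).
    """
    if "&" not in hybrid:
        raise AdapterError(f"hybridDP without '&': {hybrid!r}")
    part1, part2 = hybrid.split("&", 1)
    opens = [start1 + t for t, c in enumerate(part1) if c == "("]
    closes = [start2 + t for t, c in enumerate(part2) if c == ")"]
    if len(opens) != len(closes) or not opens:
        raise AdapterError(f"unbalanced hybridDP: {hybrid!r}")
    return tuple((opens[t], closes[len(closes) - 1 - t]) for t in range(len(opens)))


def external_predictor_adapter(
    seq1: str,
    seq2: str,
    core1,
    core2,
    mask1,
    mask2,
    command_template: str,
    config: Config | None = None,
    polarity: str = "positive",
):
    """Run the external predictor on one instance.

    Returns validated duplexes (energy-ascending, re-ranked); raises
    :class:`AdapterError` when the tool is missing, exits non-zero or
    emits unparseable output.
    """
    config = config or Config()
    with tempfile.TemporaryDirectory(prefix="rriclass_adapter_") as tmp:
        tmp = Path(tmp)
        (tmp / "query.fa").write_text(f">side1\n{seq1}\n")
        (tmp / "target.fa").write_text(f">side2\n{seq2}\n")
        out_csv = tmp / "out.csv"
        cmd = command_template.format(
            query=tmp / "query.fa",
            target=tmp / "target.fa",
            seed_len=config.seed_len,
            n=config.n_suboptimals,
            out=out_csv,
        )
        try:
            proc = subprocess.run(
                cmd, shell=True, capture_output=True, text=True
            )
        except OSError as exc:
            raise AdapterError(f"external predictor failed to start: {exc}")
        if proc.returncode != 0:
            raise AdapterError(
                f"external predictor exited {proc.returncode}: {proc.stderr.strip()}"
            )
        text = out_csv.read_text() if out_csv.exists() else proc.stdout
        try:
            rows = list(csv.DictReader(text.splitlines()))
        except csv.Error as exc:
            raise AdapterError(f"unparseable predictor output: {exc}")
        if rows and not {"start1", "end1", "start2", "end2", "hybridDP", "E"} <= set(
            rows[0]
        ):
            raise AdapterError(
                f"predictor output missing columns, got {sorted(rows[0])}"
            )

    if mask1 is None:
        mask1 = np.zeros(len(seq1), dtype=bool)
    if mask2 is None:
        mask2 = np.zeros(len(seq2), dtype=bool)
    P, _ = pair_matrices(seq1, seq2, mask1, mask2, config.pair_energies)
    S = seed_eligibility(P, core1, core2, polarity)

    duplexes = []
    for row in rows:
        try:
            pairs = parse_hybrid_dp(
                row["hybridDP"], int(row["start1"]) - 1, int(row["start2"]) - 1
            )
            energy = float(row["E"])
        except (KeyError, ValueError) as exc:
            raise AdapterError(f"bad predictor row {row!r}: {exc}")
        seed = _seed_annotation(pairs, S, config.seed_len)
        candidate = Duplex(pairs=pairs, energy=energy, seed=seed or (0, 0))
        problems = validate_duplex(
            candidate, seq1, seq2, core1, core2, mask1, mask2, config, polarity
        )
        # the adapter's thermodynamic energies are authoritative; only
        # structural violations reject a duplex
        problems = [p for p in problems if not p.startswith("energy mismatch")]
        if seed is None:
            problems.append("no valid seed run")
        if problems:
            logger.warning(
                "adapter duplex rejected (%s): %s", "; ".join(sorted(set(problems))), row
            )
            continue
        duplexes.append(candidate)
    duplexes.sort(key=lambda d: (d.energy, d.pairs))
    return [
        Duplex(pairs=d.pairs, energy=d.energy, seed=d.seed, rank=r + 1)
        for r, d in enumerate(duplexes[: config.n_suboptimals])
    ]
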