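#!/usr/bin/env python
"""OPTIONAL, UNTESTED: family-scale benchmark against Rfam seed alignments.

Downloads a seed alignment (network required), predicts every member
sequence, and reports base-pair sensitivity plus stack-level PPV and
sensitivity against the consensus structure.  This script is provided for
completeness only: it needs network access and an Rfam accession, it is not
exercised by the test suite, and its numbers are not part of any automated
check.

Usage:
    python scripts/rfam_benchmark.py RF00005 --limit 20
"""

from __future__ import annotations

import argparse
import gzip
import io
import sys
import urllib.request

RFAM_URL = "https://rfam.org/family/{acc}/alignment?acc={acc}&format=stockholm&download=1"


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("accession", help="Rfam family accession, e.g. RF00005")
    ap.add_argument("--limit", type=int, default=0, help="Max sequences (0 = all).")
    args = ap.parse_args()

    from coaxfold import (
        build_orderings,
        evaluate_prediction,
        find_helix_candidates,
        parse_stockholm,
    )
    from coaxfold.dp import fill_tables, traceback
    from coaxfold.geometry import enumerate_coax_pairs

    url = RFAM_URL.format(acc=args.accession)
    print(f"fetching {url}", file=sys.stderr)
    raw = urllib.request.urlopen(url, timeout=120).read()
    if raw[:2] == b"\x1f\x8b":
        raw = gzip.decompress(raw)
    records = parse_stockholm(raw.decode())

    tp = fn = 0
    rows = []
    for i, (rid, (seq, ref)) in enumerate(records.items()):
        if args.limit and i >= args.limit:
            break
        cands = find_helix_candidates(seq)
        index = build_orderings(cands)
        coax = enumerate_coax_pairs(index, seq)
        pred = traceback(fill_tables(index, coax), index, coax)
        bp, _ = evaluate_prediction(pred, ref, index=index)
        tp += bp.tp
        fn += bp.fn
        sens = "NA" if bp.sensitivity is None else f"{bp.sensitivity:.2f}"
        rows.append(f"{rid}\t{bp.tp}\t{bp.fn}\t{sens}")
    print("id\ttp\tfn\tsensitivity")
    print("\n".join(rows))
    if tp + fn:
        print(f"# overall base-pair sensitivity: {100.0 * tp / (tp + fn):.2f}%")


if __name__ == "__main__":
    main()
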