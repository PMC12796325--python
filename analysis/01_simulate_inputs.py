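#!/usr/bin/env python
"""Generate every synthetic input stream at the documented study conditions.

Writes the cruise cast table, the multi-decadal cast + bottle record, the
annotated transcript count matrix, the polony/flow-cytometry table and the
monthly virus/host pairs under results/simulated/, in the exact formats the
downstream drivers and CLIs consume.
"""

import argparse
from pathlib import Path

from somshunt import cli


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", default="results/simulated")
    args = ap.parse_args()
    out = Path(args.out)
    for what in ("cruise", "climatology", "counts", "polony", "vlp"):
        rc = cli.main(["simulate", what, "--seed", str(args.seed),
                       "--out", str(out / what)])
        assert rc == 0, what
        print(f"wrote {what} inputs under {out / what}")


if __name__ == "__main__":
    main()
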