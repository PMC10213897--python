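#!/usr/bin/env python
"""Regenerate the bundled calibrated anatomy (data/default_anatomy.yaml).

Runs the least-squares calibration of the free geometric parameters against
the published force-proportionality coefficients and condylar path lengths,
starting from the currently bundled parameter set, and overwrites the
bundled file on convergence. Maintenance tool; the installed package never
calibrates at run time.

Usage: python scripts/calibrate_default.py [--n-steps 80] [--max-nfev 200]
"""

import argparse
from pathlib import Path

from chewsim import anatomy


def main(argv=None):
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--n-steps", type=int, default=80)
    parser.add_argument("--max-nfev", type=int, default=200)
    parser.add_argument(
        "--out",
        type=Path,
        default=Path(__file__).resolve().parents[1]
        / "src/chewsim/data/default_anatomy.yaml",
    )
    args = parser.parse_args(argv)
    model = anatomy.build_default("right")
    report = anatomy.calibrate(model, n_steps=args.n_steps, max_nfev=args.max_nfev)
    print(report.summary())
    if not report.converged:
        raise SystemExit("calibration did not converge; bundled file unchanged")
    anatomy.save_params(model.params, args.out)
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
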