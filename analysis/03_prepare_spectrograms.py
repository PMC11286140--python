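"""Build the uniform-length, onset-aligned mel-spectrogram set.

Calls longer than 1.25 s are excluded (none at the default generator
settings), every spectrogram is padded at the dB floor to the longest call
and shifted so its energy onset sits at frame 0. The prepared set is
persisted as an .npz archive under scratch/ with a CSV index under
results/.

Usage: python analysis/03_prepare_spectrograms.py
"""

import argparse
from pathlib import Path

from zebrarep.specprep import mel_spectrogram, pad_and_align, save_spectrogram_set
from zebrarep.synth import read_wav
from zebrarep.workbench import apply_inclusion_rules, load_annotations


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--datadir", type=Path, default=Path("scratch/dataset"))
    args = ap.parse_args()

    records, _ = load_annotations(args.datadir / "annotations.csv")
    kept, log = apply_inclusion_rules(records, "repertoire")
    specs = [mel_spectrogram(read_wav(args.datadir / r.file), call_id=r.call_id)
             for r in kept]
    specs = pad_and_align(specs)

    Path("results").mkdir(exist_ok=True)
    Path("scratch").mkdir(exist_ok=True)
    save_spectrogram_set(specs, "scratch/spectrograms.npz",
                         "results/03_spectrogram_index.csv")
    log.as_frame().to_csv("results/03_exclusions.csv", index=False)
    print(f"prepared {len(specs)} spectrograms of shape {specs[0].matrix.shape} "
          f"({len(log)} calls excluded as too long)")


if __name__ == "__main__":
    main()
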