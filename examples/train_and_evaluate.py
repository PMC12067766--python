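"""Train a small cross-validated ensemble on synthetic images and score it.

A reduced run (20 images, k=2, 12 epochs, 64-px frames) that finishes in
seconds on one CPU; the full desk-scale study used by
scripts/acceptance.py is the same code with 80 images at 128 px and 15
epochs.
"""

from rrseg import (SynthConfig, TrainingConfig, UNetConfig, evaluate_dataset,
                   generate_dataset, make_folds, threshold_probabilities)
from rrseg.training import train_ensemble

config = SynthConfig(image_size_px=64, n_rods=(1, 4), n_rings=(1, 4), seed=7)
dataset = generate_dataset(config, n_images=20)
pairs = [(img, masks) for img, masks, _ in dataset]

folds = make_folds([img.id for img, _ in pairs], k=2, seed=7)
ensemble, heldout, histories = train_ensemble(
    pairs, folds, UNetConfig(depth=2, base_channels=8),
    TrainingConfig(epochs=12, batch_size=4, seed=7))
print("final training loss per member:",
      [f"{h.train[-1]:.4f}" for h in histories])

truths = {img.id: masks for img, masks, _ in dataset}
predictions = {i: threshold_probabilities(m, ensemble.threshold)
               for i, m in heldout.items()}
report = evaluate_dataset(predictions, heldout, truths,
                          config.pixel_size_um, policy="exclude")
print(report.aggregate.to_string(index=False))
print("\nEvery image is scored by the member that never saw it in training "
      "(cross-validated coverage); Dice/Jaccard compare thresholded masks "
      "with ground truth, AUC scores the raw probability maps.")
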