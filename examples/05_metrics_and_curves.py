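"""Classification and segmentation metrics on small hand-checkable inputs.

AUC is the normalized Mann-Whitney statistic; the confusion metrics use a
training-set Youden cutoff; decision-curve analysis reports net benefit
against the treat-all and treat-none policies; the segmentation bundle
covers Dice, IoU and the average symmetric surface distance (ASSD).
"""

import numpy as np

from vfmgl.evaluation import (ScoredPredictions, SegPair, assd,
                              confusion_metrics, dca_curve, dice_iou)
from vfmgl.evaluation import auc as auc_fn

y = np.array([0, 1, 0, 1, 1, 0, 1, 0])
s = np.array([0.2, 0.9, 0.4, 0.7, 0.6, 0.1, 0.3, 0.5])
preds = ScoredPredictions(y, s)
print(f"AUC: {auc_fn(preds):.3f}  (fraction of correctly ranked +/- pairs)")
m = confusion_metrics(preds)
print(f"Youden cutoff {m['cutoff']:.2f}: sensitivity {m['sensitivity']:.2f}, "
      f"specificity {m['specificity']:.2f}, accuracy {m['accuracy']:.2f}")

d = dca_curve(preds, thresholds=np.array([0.2, 0.4, 0.6]))
print("\nnet benefit vs threshold (model / treat-all):")
for _, row in d.iterrows():
    print(f"  p_t={row['threshold']:.1f}: {row['net_benefit']:+.3f} / "
          f"{row['treat_all']:+.3f}")

a = np.zeros((16, 16), bool); a[4:10, 4:10] = True
b = np.zeros((16, 16), bool); b[6:12, 5:11] = True
pair = SegPair(a, b)
dice, iou = dice_iou(pair)
print(f"\nsegmentation: dice {dice:.3f}, iou {iou:.3f}, "
      f"assd {assd(pair):.2f} px (0 = identical boundaries)")
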