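"""Accuracy assessment of a rapeseed / non-rapeseed classification map.

The 2x2 confusion matrix counts reference pixels (columns) against mapped
pixels (rows).  Overall accuracy is the diagonal fraction; user accuracy is
per mapped class, producer accuracy per reference class; kappa corrects for
chance agreement.
"""

import numpy as np

from rapeyield import ConfusionMatrix2, confusion_metrics
from rapeyield.accuracy import format_report

counts = np.array([[27418, 2226], [4163, 21249]])  # rows: NOR, OR mapped
metrics = confusion_metrics(ConfusionMatrix2(counts))
print(format_report(metrics))
print("\nA kappa of", round(metrics["kappa"], 2),
      "indicates substantial agreement beyond chance.")
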