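"""Train the counseling-skill coder on synthetic labeled utterances, label
a few statements, and quantify agreement with the ground truth.

Run:  python examples/02_skill_coding.py
"""

import numpy as np

from clientbot.coder import cohen_kappa, train_skill_classifier
from clientbot.synthetic import generate_labeled_utterances

train = generate_labeled_utterances(100, seed=0)   # 100 per class, 4 classes
test = generate_labeled_utterances(100, seed=1)    # a fresh seed's set
coder = train_skill_classifier(train, seed=0)

acc = np.mean([coder.classify(text) == label for text, label in test])
print(f"held-out accuracy on a fresh generator seed: {acc:.3f} "
      "(fraction of 400 utterances labeled with their true skill code)")

truth = [label for _, label in test]
pred = [coder.classify(text) for text, _ in test]
rep = cohen_kappa(truth, pred)
print(f"kappa vs truth: {rep.kappa:.3f} "
      f"(chance-corrected agreement; observed {rep.observed_agreement:.3f}, "
      f"expected by chance {rep.expected_agreement:.3f})")

for text in ["what brings you here today ?",
             "do you smoke ?",
             "so it sounds like you are worried that drinking is getting in "
             "the way of the things you would like to be doing in life .",
             "ok ."]:
    print(f"  {coder.classify(text).value:16s} <- {text}")
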