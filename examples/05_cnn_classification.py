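"""Train the 16-layer / 3-convolution CNN classifier on phantoms.

The network maps a grayscale image straight to three class probabilities;
no hand-crafted features. Desk-scale budget: tiny images, short training.
"""

import numpy as np

from busecho import NetConfig, build_classifier, train_classifier
from busecho.cnn import predict_proba
from busecho.phantom import PhantomParams, generate_phantom

# three classes separated by overall echogenicity
images, labels = [], []
for cls, bg in enumerate((190.0, 140.0, 90.0)):
    for i in range(8):
        p = PhantomParams(image_size=(32, 32), class_label=0, background_mean=bg,
                          lesion_mean=bg - 1, seed=100 * cls + i)
        images.append(generate_phantom(p)[0])
        labels.append(cls)
images, labels = np.stack(images), np.array(labels)

cfg = NetConfig(task="classify", image_size=(32, 32), iterations=150,
                batch_size=12, learning_rate=3e-3, seed=0)
net = build_classifier(cfg)
print("architecture:", " -> ".join(net.layer_names))
print("parameters:", net.n_parameters())

net, trace = train_classifier(net, images, labels)
print(f"final training loss {trace.loss[-1]:.3f}, "
      f"accuracy {trace.accuracy[-1]:.2f} after {len(trace)} iterations")
probs = predict_proba(net, images)
print(f"training-set accuracy of restored best checkpoint: "
      f"{np.mean(probs.argmax(axis=1) == labels):.2f}")
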