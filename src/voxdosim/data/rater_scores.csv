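tissue,rater,dsc,hausdorff_mm
Gallbladder,segmentor1,0.86,0.55
Gallbladder,segmentor2,0.82,0.70
Gallbladder,segmentor3,0.94,0.28
Urinary bladder,segmentor1,0.88,1.66
Urinary bladder,segmentor2,0.92,1.01
Urinary bladder,segmentor3,0.96,0.57
Kidney left,segmentor1,0.96,0.34
Kidney left,segmentor2,0.96,0.39
Kidney left,segmentor3,0.98,0.18
Lung right,segmentor1,0.99,0.12
Lung right,segmentor2,0.99,0.15
Lung right,segmentor3,0.99,0.08
Liver,segmentor1,0.99,0.15
Liver,segmentor2,0.99,0.23
Liver,segmentor3,0.99,0.05
Heart muscle,segmentor1,0.96,0.10
Heart muscle,segmentor2,0.99,0.01
Heart muscle,segmentor3,0.99,0.01
Spleen,segmentor1,0.81,2.09
Spleen,segmentor2,0.98,0.27
Spleen,segmentor3,0.99,0.02
Uterus,segmentor1,0.99,0.04
Uterus,segmentor2,0.86,0.35
Uterus,segmentor3,0.95,0.14
Vagina,segmentor1,0.98,0.04
Vagina,segmentor2,0.92,0.15
Vagina,segmentor3,0.90,0.19
Humerus right,segmentor1,0.98,0.11
Humerus right,segmentor2,0.99,0.05
Humerus right,segmentor3,0.99,0.01
Tibia right,segmentor1,0.98,0.12
Tibia right,segmentor2,0.99,0.03
Tibia right,segmentor3,0.99,0.04
Femur right,segmentor1,0.94,0.35
Femur right,segmentor2,0.92,0.49
Femur right,segmentor3,0.99,0.01
Fibula right,segmentor1,0.96,0.80
Fibula right,segmentor2,0.99,0.01
Fibula right,segmentor3,0.99,0.01
Ulna right,segmentor1,0.97,0.08
Ulna right,segmentor2,0.95,0.16
Ulna right,segmentor3,0.99,0.02
"Air nose, sinuses",segmentor1,0.94,0.13
"Air nose, sinuses",segmentor2,0.97,0.06
"Air nose, sinuses",segmentor3,0.97,0.06
Vitreous body right,segmentor1,0.96,0.18
Vitreous body right,segmentor2,0.95,0.25
Vitreous body right,segmentor3,0.98,0.11
Radius right,segmentor1,0.97,0.16
Radius right,segmentor2,0.97,0.16
Radius right,segmentor3,0.99,0.01
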