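tissue,is_liquid,density_kg_m3,heat_capacity_J_kg_C,thermal_conductivity_W_m_C,metabolic_rate_W_kg,permittivity_ratio,permittivity_child,conductivity_ratio,conductivity_child_S_m,perfusion_ratio,perfusion_child_ml_min_kg
Adrenal gland,0,1050,3600,0.52,5.0,1.23,76.60,1.32,0.89,1.72,2505
Air,0,1.2,1005,0.026,0.0,1.00,1.00,1.00,0.00,1.00,0
Bile,1,1010,4000,0.57,0.0,1.00,74.97,1.00,1.67,1.00,0
Blood,1,1050,3617,0.52,0.0,1.00,65.70,1.00,1.32,1.00,10000
Blood vessel wall,0,1050,3600,0.5,1.0,1.24,60.04,1.36,0.73,1.00,150
Bone (Cortical),0,1908,1313,0.32,0.15,1.84,24.78,2.42,0.20,1.72,17
Bone marrow (red),0,1029,2666,0.28,0.51,1.24,15.07,1.36,0.24,1.72,232
Brain (grey matter),0,1045,3696,0.55,15.5,1.33,79.79,1.51,1.04,2.21,1685
Brain (white matter),0,1041,3583,0.48,4.9,1.33,58.19,1.51,0.62,2.21,468
Bronchi,0,1050,3600,0.5,1.0,1.24,56.28,1.36,0.83,1.72,409
Cartilage,0,1050,3600,0.5,1.0,1.24,58.11,1.36,0.75,1.72,409
Cerebellum,0,1045,3653,0.51,12.8,1.33,79.45,1.51,1.47,1.72,60
Cerebrospinal fluid,1,1010,4000,0.57,0.0,1.00,72.80,1.00,2.22,2.21,1699
Commissura anterior,0,1041,3583,0.48,4.9,1.33,58.19,1.51,0.62,0.00,0
Commissura posterior,0,1041,3583,0.48,4.9,1.33,58.19,1.51,0.62,2.21,468
Connective tissue,0,1050,3600,0.5,1.0,1.24,59.59,1.36,0.73,1.72,63.9
Diaphragm,0,1090,3421,0.49,0.96,1.20,69.62,1.36,1.05,1.72,170
Dura,0,1050,3600,0.5,1.0,1.33,63.72,1.51,1.21,2.21,838
Esophagus,0,1090,3421,0.49,0.96,1.24,85.34,1.36,1.32,1.72,326
Eye (aqueous humor),1,1010,4000,0.57,0.0,1.00,72.80,1.00,2.22,1.00,0
Eye (cornea),0,1050,3600,0.5,1.0,1.24,76.27,1.36,1.56,1.00,0
Eye (lens),0,1050,3600,0.5,1.0,1.24,47.65,1.36,0.48,1.00,0
Eye (retina),0,1045,3696,0.55,15.5,1.33,79.79,1.51,1.04,1.72,412
Eye (sclera),0,1050,3600,0.5,1.0,1.24,73.16,1.36,1.33,2.21,838
Eye (vitreous humor),1,1010,4000,0.57,0.0,1.00,69.02,1.00,1.52,0.00,0
Fat,0,911,2348,0.21,0.51,1.24,14.58,1.36,0.10,1.72,56
Gallbladder,0,1050,3600,0.5,1.0,1.00,62.99,1.00,1.12,1.72,52
Heart muscle,0,1081,3686,0.56,33.0,1.20,82.99,1.36,1.23,1.13,1158
Hippocampus,0,1045,3696,0.55,15.5,1.33,79.79,1.51,1.04,2.21,1685
Hypophysis,0,1050,3600,0.52,5.0,1.23,76.89,1.32,1.13,2.21,1952
Hypothalamus,0,1045,3696,0.55,15.5,1.33,79.79,1.51,1.04,2.21,1685
Intervertebral Disc,0,1050,3600,0.5,1.0,1.24,58.65,1.36,1.24,1.72,60
Intestine contents,1,1010,4000,0.57,0.0,1.00,58.24,1.00,0.77,1.00,0
Kidney,0,1066,3763,0.53,18.1,1.24,87.67,1.36,1.39,1.21,4575
Large intestine,0,1050,3600,0.5,1.0,1.24,80.80,1.36,1.10,1.23,943
Larynx,0,1050,3600,0.5,1.0,1.24,58.11,1.36,0.75,1.72,60
Liver,0,1079,3540,0.52,9.9,1.21,64.93,1.25,0.76,1.20,1034
Lung,0,394,3886,0.39,1.0,1.24,30.79,1.36,0.48,1.72,689
Mandible,0,1908,1313,0.32,0.15,1.84,24.78,2.42,0.20,1.72,17
Medulla oblongata,0,1045,3653,0.51,12.8,1.33,79.45,1.51,1.47,2.21,1232
Midbrain,0,1045,3653,0.51,12.8,1.33,79.45,1.51,1.47,2.21,1232
Mucous membrane,0,1050,3600,0.5,1.0,1.20,69.62,1.36,1.05,1.72,1020
Muscle,0,1090,3421,0.49,0.96,1.20,69.62,1.36,1.05,1.13,41
Nerve,0,1041,3583,0.48,4.9,1.24,45.88,1.36,0.57,1.72,275
Ovary,0,1050,3600,0.52,5.0,1.24,76.25,1.36,1.28,1.72,405
Pancreas,0,1050,3600,0.52,5.0,1.23,76.89,1.32,1.13,1.37,1049
Pineal body,0,1050,3600,0.52,5.0,1.23,76.89,1.32,1.13,2.21,1952
Placenta,0,1050,3600,0.5,1.0,1.00,65.70,1.00,1.32,1.72,2920
Pons,0,1045,3653,0.51,12.8,1.33,79.45,1.51,1.47,2.21,1232
Salivary gland,0,1050,3600,0.52,5.0,1.23,95.99,1.32,0.95,1.72,658
SAT (subcutaneous fat),0,911,2348,0.21,0.51,1.24,14.58,1.36,0.10,1.72,56
Skin,0,1109,3391,0.37,1.65,1.29,64.58,1.47,0.94,1.49,159
Skull cortical,0,1908,1313,0.32,0.15,1.84,24.78,2.42,0.20,1.72,17
Small intestine,0,1050,3600,0.5,1.0,1.24,86.76,1.36,2.50,1.23,1264
Spinal cord,0,1041,3583,0.48,4.9,1.24,45.88,1.36,0.57,1.72,275
Spleen,0,1050,3600,0.5,1.0,1.24,82.68,1.36,1.32,1.27,1972
Stomach,0,1090,3421,0.49,0.96,1.24,85.34,1.36,1.32,1.23,565
Tendon/ligament,0,1050,3600,0.5,1.0,1.24,59.59,1.36,0.73,1.72,50
Thalamus,0,1045,3696,0.55,15.5,1.33,79.79,1.51,1.04,2.21,1510
Thymus,0,1050,3600,0.52,5.0,1.24,66.67,1.36,0.00,1.72,424
Thyroid gland,0,1050,3600,0.52,5.0,1.23,76.89,1.32,1.13,1.72,9659
Tongue,0,1090,3421,0.49,0.96,1.24,73.16,1.36,1.01,1.13,88
Tooth,0,1908,1313,0.32,0.15,1.84,24.78,2.42,0.20,1.00,0
Trachea,0,1050,3600,0.5,1.0,1.24,56.28,1.36,0.83,1.72,60
Uterus,0,1090,3421,0.49,0.96,1.24,60.04,1.36,0.73,1.72,787
Urinary bladder wall,0,1090,3421,0.49,0.96,1.24,24.96,1.36,0.43,1.72,134
Urine,1,1010,4000,0.57,0.0,1.00,49.95,1.00,1.75,1.00,0
Vagina,0,1090,3421,0.49,0.96,1.24,80.80,1.36,1.10,1.72,168
Vertebrae,0,1908,1313,0.32,0.15,1.84,24.78,2.42,0.20,1.72,17
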