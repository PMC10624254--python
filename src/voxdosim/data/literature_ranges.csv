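tissue,measurement,low,high,source,note
Lung right,weight_g,120,320,Haddad2001,
Lung right,weight_g,150,300,ICRP89,
Lung left,weight_g,120,320,Haddad2001,
Brain,weight_g,1000,1100,Haddad2001,
Brain,weight_g,950,1310,ICRP89,
Brain CSF,volume_cm3,110,120,Matsuzawa2001,
Heart,weight_g,50,90,Haddad2001,
Heart,weight_g,50,85,ICRP89,
Kidneys combined,weight_g,70,110,Haddad2001,
Kidney right,length_cm,40,70,Konus1998,unit_conflict_weight_g_in_text
Kidney left,length_cm,40,70,Konus1998,unit_conflict_weight_g_in_text
Liver,weight_g,330,570,ICRP89,
Liver,weight_g,400,500,Haddad2001,
Liver right lobe,length_cm,45,95,Konus1998,
Pancreas,weight_g,0,52,Haddad2001,upper_bound_only
Pancreas,weight_g,20,35,ICRP89,
Spleen,weight_g,29,50,ICRP89,
Spleen,weight_g,30,60,Haddad2001,
Spleen,length_cm,40,75,Konus1998,
Stomach,weight_g,20,48,Haddad2001,
Stomach,weight_g,20,50,ICRP89,
Thymus,weight_g,25,35,Haddad2001,
Thymus,weight_g,30,30,ICRP89,point_value
Ovaries,volume_cm3,0.6,3.6,Kelsey2013,
Ovaries,weight_g,0.8,2,ICRP89,
Sternal bone,length_cm,7.5,7.5,Xie2014,point_reference
Radius/humerus,ratio,0.71,0.78,Pujol2014,
Tibia/femur,ratio,0.78,0.84,Pujol2014,
Humerus/femur,ratio,0.67,0.75,Pujol2014,
Radius/tibia,ratio,0.61,0.70,Pujol2014,
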