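table,parameter,compartment,unit,kind,center,sd,q25,q75,source_label
histomorphometry,Bone volume/tissue volume,,%,mean_sd,17.7,2.6,,,pediatric reference (age range 1.5-6.9 years)
histomorphometry,Trabecular thickness,,µm,mean_sd,101,11,,,pediatric reference (age range 1.5-6.9 years)
histomorphometry,Trabecular number,,1/mm,mean_sd,1.77,0.31,,,pediatric reference (age range 1.5-6.9 years)
histomorphometry,Cortical width,,µm,mean_sd,0.70,0.28,,,pediatric reference (age range 1.5-6.9 years)
histomorphometry,Osteoid thickness,,µm,mean_sd,5.8,1.4,,,pediatric reference (age range 1.5-6.9 years)
histomorphometry,Osteoid surface/bone surface,,%,mean_sd,34.0,6.7,,,pediatric reference (age range 1.5-6.9 years)
histomorphometry,Osteoid volume/bone volume,,%,mean_sd,3.97,1.19,,,pediatric reference (age range 1.5-6.9 years)
histomorphometry,Osteoblast surface/bone surface,,%,mean_sd,8.5,4.1,,,pediatric reference (age range 1.5-6.9 years)
histomorphometry,Eroded surface/bone surface,,%,mean_sd,14.8,4.4,,,pediatric reference (age range 1.5-6.9 years)
histomorphometry,Osteoclast surface/bone surface,,%,mean_sd,1.11,0.75,,,pediatric reference (age range 1.5-6.9 years)
histomorphometry,Adipocyte area/marrow area,,%,none,,,,,not defined
bmdd,CaMean,cancellous,wt% Ca,mean_sd,22.48,0.73,,,healthy children (n=50)
bmdd,CaPeak,cancellous,wt% Ca,mean_sd,23.39,0.70,,,healthy children (n=50)
bmdd,CaWidth,cancellous,Δ wt% Ca,median_iqr,3.64,,3.47,3.99,healthy children (n=50)
bmdd,CaLow,cancellous,% bone area,median_iqr,5.57,,4.78,6.80,healthy children (n=50)
bmdd,CaHigh,cancellous,% bone area,median_iqr,1.52,,0.62,2.22,healthy children (n=50)
bmdd,CaMean,cortical,wt% Ca,mean_sd,21.86,1.15,,,healthy children (n=50)
bmdd,CaPeak,cortical,wt% Ca,mean_sd,22.67,1.21,,,healthy children (n=50)
bmdd,CaWidth,cortical,Δ wt% Ca,median_iqr,4.07,,3.73,4.68,healthy children (n=50)
bmdd,CaLow,cortical,% bone area,median_iqr,6.86,,5.06,11.48,healthy children (n=50)
bmdd,CaHigh,cortical,% bone area,median_iqr,1.01,,0.44,1.89,healthy children (n=50)
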