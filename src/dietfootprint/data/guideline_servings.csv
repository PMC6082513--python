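group,unit,1000,1200,1400,1600,1800,2000,2200,2400,2600,2800,3000,3200
fruit,cups,1.0,1.0,1.5,1.5,1.5,2.0,2.0,2.0,2.0,2.5,2.5,2.5
vegetables,cups,1.0,1.5,1.5,2.0,2.5,2.5,3.0,3.0,3.5,3.5,4.0,4.0
grains,oz_eq,3.0,4.0,5.0,5.0,6.0,6.0,7.0,8.0,9.0,10.0,10.0,10.0
whole_grain_portion,oz_eq,1.5,2.0,2.5,3.0,3.0,3.0,3.5,4.0,4.5,5.0,5.0,5.0
meat_beans,oz_eq,2.0,3.0,4.0,5.0,5.0,5.5,6.0,6.5,6.5,7.0,7.0,7.0
milk,cups,2.0,2.0,2.0,3.0,3.0,3.0,3.0,3.0,3.0,3.0,3.0,3.0
oils,tsp,3.0,4.0,4.0,5.0,5.0,6.0,6.0,7.0,8.0,8.0,10.0,10.0
discretionary,kcal,165,171,171,132,195,267,290,362,410,426,512,648
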