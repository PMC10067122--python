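pt,group
Arrhythmia,unspecified rate/rhythm
Tachycardia,unspecified rate/rhythm
Bradycardia,unspecified rate/rhythm
Tachyarrhythmia,unspecified rate/rhythm
Sinus tachycardia,unspecified rate/rhythm
Sinus bradycardia,unspecified rate/rhythm
Atrial flutter,atrial arrhythmia
Atrial fibrillation,atrial arrhythmia
Arrhythmia supraventricular,supraventricular tachycardia
Supraventricular tachycardia,supraventricular tachycardia
Ventricular arrhythmia,ventricular arrhythmia
Ventricular tachycardia,ventricular arrhythmia
Ventricular extrasystoles,ventricular arrhythmia
Ventricular fibrillation,ventricular arrhythmia
Conduction disorder,conduction disease
Atrioventricular block,conduction disease
Atrioventricular block second degree,conduction disease
Atrioventricular block complete,conduction disease
Bundle branch block left,conduction disease
Bundle branch block right,conduction disease
Electrocardiogram QT prolonged,QT prolongation
Sudden death,cardiac arrest/sudden death
Cardiac arrest,cardiac arrest/sudden death
Sudden cardiac death,cardiac arrest/sudden death
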